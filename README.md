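# airscore

Joint effects of correlated environmental exposures on a rare time-to-event
outcome, with genetic effect modification.  The package implements, as a
tested library, the full inference chain used in multi-pollutant dementia
epidemiology: a **cross-validated weighted air-pollution score**, pooled
survival inference, polygenic and *APOE* ε4 risk stratification, and
multiplicative/additive gene–environment interaction — together with a
calibrated synthetic-cohort generator so every stage can be exercised and
validated end to end.

## The problem

Ambient air pollution is a mixture: PM<sub>2.5</sub>, PM<sub>10</sub>,
NO<sub>2</sub> and NO<sub>x</sub> are so strongly rank-correlated
(ρ ≈ 0.8–0.95) that putting all four into one Cox model produces unstable,
sign-flipping coefficients.  A common remedy summarizes the mixture as a
weighted score

```
score = (α̂_PM2.5·PM2.5 + α̂_PM10·PM10 + α̂_NO2·NO2 + α̂_NOx·NOx) × 4 / Σ α̂
```

with weights α̂ taken from Cox fits.  Estimating the weights and the
score–outcome association on the same subjects reuses the data and inflates
both effect sizes and significance.  The procedure implemented here avoids
that: subjects are randomly split into *k* = 10 batches; weights fitted on
nine batches score the held-out batch, so every subject's score is
out-of-fold.  The ten held-out association estimates (hazard ratio per IQR
of the score, and quartile contrasts on a pooled out-of-fold scale) are
combined by fixed-effect inverse-variance weighting,

&nbsp;&nbsp;β̂ = Σ wᵢβ̂ᵢ / Σ wᵢ, wᵢ = 1/SEᵢ², SE = (Σ wᵢ)^(−1/2),

and the combined p-value uses the **harmonic mean p-value** (HMP),
p̊ = L / Σ (1/pᵢ), calibrated through the tail of the Landau distribution
(location ln L + 1 − γ + ln(π/2), scale π/2), which is robust to dependence
among the batch p-values.

Genetic susceptibility enters through a 29-SNP polygenic risk score
(PRS = Σ Gⱼβ̂ⱼ over risk-allele dosages) and *APOE* ε4 dosage derived from
the rs429358/rs7412 haplotypes (ε4 = C–C, ε3 = T–C, ε2 = T–T).  Joint
score-quartile × genetic-tertile stratification (12 cells, low/low
reference), the product-term hazard ratio, and additive interaction
(RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1, AP = RERI/HR₁₁, delta-method CIs) quantify
effect modification.

## Worked example

```bash
python examples/02_pollution_score.py
```

generates a 30,000-subject cohort under the default calibration (true score
effect HR 1.13 per IQR) and runs the 10-batch pipeline; the run prints

```
pooled HR per IQR: 1.128 (95% CI 1.007-1.263)
harmonic mean p  : 0.1594
calibrated p     : 0.2987
```

followed by the pooled quartile contrasts (Q4 vs Q1 prints 1.260 here).
The pooled hazard ratio is the inverse-variance combination of the ten
held-out estimates and scatters around the configured truth of 1.13; the
calibrated p-value is the HMP-combined evidence across batches — at this
deliberately modest sample size (~450 events) a true HR of 1.13 is not
reliably significant, which is itself a faithful property of the design.  `examples/01_simulate_cohort.py`
prints the baseline table of the generator (exposure means/IQRs
9.9/2.3, 14.8/3.2, 18.1/6.9, 26.9/12.0 µg/m³; ~1.5% events; median
follow-up ~13.4 years), and `examples/03_genetics_and_interaction.py` the
genetic hazard ratios, the 12-cell joint table and the interaction
statistics.

A thin CLI mirrors the library for shell use:

```bash
airscore simulate --out cohort.tsv --n 20000 --seed 1
airscore run --cohort cohort.tsv --out-dir results/
airscore subgroups --cohort cohort.tsv --out subgroups.tsv
```

## Layout

- `src/airscore/cohort.py` — seeded synthetic-cohort generator (log-normal
  exposures via a Gaussian copula, covariate mix, binomial SNP dosages,
  phased APOE haplotypes, exponential proportional-hazards outcomes with
  calibrated baseline hazard and administrative censoring)
- `src/airscore/survival.py` — Cox partial-likelihood fitting (Efron or
  Breslow ties), Schoenfeld PH diagnostics, restricted cubic splines and a
  nonlinearity LRT, per-IQR/quartile effect summaries, Kaplan–Meier/log-rank
- `src/airscore/genetics.py` — PRS panels and arithmetic, quantile risk
  groups, APOE haplotype mapping
- `src/airscore/score.py` — fold assignment, fold weights, score formula,
  held-out association, IVW pooling, HMP calibration
- `src/airscore/interaction.py` — 12-cell joint strata, product-term and
  RERI/AP interaction
- `src/airscore/pipeline.py`, `cli.py` — end-to-end runs, subgroup and
  sensitivity variants, tidy outputs with provenance
- `docs/methods.md` — model assumptions, calibration choices, limitations
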