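# Methods

This note documents the statistical models behind `airscore`, the
assumptions and defaults of its synthetic-cohort generator, the numerical
choices in the estimation code, and what the validation suite does and does
not establish.

## 1. The estimand and the cross-validated score

The analysis concerns the joint effect of four strongly collinear ambient
pollutant concentrations (PM2.5, PM10, NO2, NOx, in µg/m³) on the hazard of
a rare incident outcome.  The joint exposure is summarized by the weighted
score

    score_i = (Σ_j α̂_j x_ij) · 4 / Σ_j α̂_j ,

with weights α̂_j equal to Cox log-hazard coefficients per unit
concentration.  The normalizer 4/Σα̂ puts the score back on an
average-concentration scale and makes it invariant to rescaling all weights
by a common factor.

**Weight source.** Because joint four-pollutant fits are unstable under
collinearity, each α̂_j comes by default from its own single-pollutant
adjusted Cox model on the training batches; a joint-fit mode is available
(`weight_mode="joint"`).

**Data-reuse control.** Subjects are randomly partitioned into k = 10
equal batches.  For each batch in turn, weights are estimated on the other
nine and the held-out batch is scored, so every subject's score is
out-of-fold; the association between score and outcome is then estimated
only on held-out data.  Per-fold estimates are combined by fixed-effect
inverse-variance weighting (folds are homogeneous by construction, so a
random-effects model would only add noise), and the ten per-fold p-values
are combined with the harmonic-mean p-value.

**Shared scale.** The per-IQR unit and the quartile cut points of the score
are computed on the pooled out-of-fold score vector, not per fold, so that
per-fold estimates are on one scale before pooling.  This choice matters:
the fold-specific normalizer 4/Σα̂ is a noisy scalar, and when the training
weights are small its magnitude (or sign) can fluctuate.  Per-fold
estimates of the per-IQR effect are invariant to each fold's scale (the
Wald statistic of a Cox coefficient is invariant to linear rescaling of the
covariate), but quartile contrasts need the common scale.  In small folds a
quartile cell can be left without events; such folds keep their per-IQR
contribution and drop only their quartile contrast (with a warning).

**Negative weights.** A training batch can produce a negative α̂_j.  The
formula is applied literally (with a warning), matching the score's
definition; `floor_negative=True` clips weights at zero instead.

**HMP calibration.** For L p-values with normalized weights w,
p̊ = Σw / Σ(w/p).  The asymptotically exact combined p-value is the upper
tail of the Landau distribution with location ln L + 1 − γ + ln(π/2) and
scale π/2 evaluated at 1/p̊ (γ is Euler's constant); for L = 1 the p-value
is returned unchanged.  The Landau tail is evaluated with
`scipy.stats.landau`, and the implementation was checked against the null
distribution of the HMP by direct Monte Carlo.

## 2. Survival estimation

`fit_cox` maximizes the Cox partial likelihood by Newton–Raphson with
step-halving, supporting Efron (default) and Breslow tie handling.  The
solver is written on suffix sums over the time-ordered sample so that a
fit at n = 45,000 with ~15 covariates and a rare outcome takes tens of
milliseconds; this is what makes 500-replicate calibration studies and
multi-seed recovery runs tractable.  Correctness is established in the test
suite three ways: equality with brute-force grid/numerical maximization of
the written-out partial likelihood on tiny instances (≤ 5 subjects, with
and without ties), agreement with lifelines to ~1e-5 on shared data sets
(including heavily tied data), and closed-form oracles on two-group
exponential designs.

Numerical details: covariate columns are centered before iteration (the
coefficients and covariance are unaffected); linear predictors are clipped
at ±200 before exponentiation; convergence requires the gradient below
1e-7·|loglik|; the line search accepts candidates within a roundoff slack
of 1e-11·|loglik|; estimates with max|β| > 80 raise a separation error, as
do constant covariates (named) and event-free data.  The covariance is the
inverse observed information at the optimum.

Diagnostics and summaries:

- **Proportional hazards** — Grambsch–Therneau correlation test of
  (scaled) Schoenfeld residuals against a transform of event time (rank by
  default), per covariate and global; validated against
  `lifelines.statistics.proportional_hazard_test` and by type-I/power
  simulation.
- **Restricted cubic splines** — Harrell's truncated-power basis,
  normalized by the squared knot span, three knots by default at the
  10th/50th/90th percentiles (knot placement is a convention; the fitted
  curve is linear beyond the boundary knots by construction).  The
  nonlinearity test is a likelihood-ratio test of the spline terms over the
  linear model.
- **Effect scales** — HR per IQR is exp(β·IQR) with the CI transformed on
  the same scale; quartile contrasts use indicator terms against Q1; the
  trend test treats the quartile index 1–4 as a single continuous covariate
  (integer scores; quartile medians would be an equally defensible choice).
- **Kaplan–Meier and log-rank** are delegated to lifelines.

## 3. Genetics

The PRS is the exact weighted dosage sum over a 29-SNP panel.  The bundled
default panel is synthetic (placeholder identifiers, frequencies spanning
0.08–0.45) with weights scaled so the population PRS variance is 1; real
GWAS weights can be loaded from a TSV.  Risk groups are value-based
quantile cuts (tertiles, or a 20/60/20 quintile scheme for sensitivity
analysis), so tied values always share a group.

APOE genotypes are reduced to ε4 dosage via the rs429358/rs7412 haplotype
map (ε4 = C–C, ε3 = T–C, ε2 = T–T; the rare C–T haplotype is counted as
non-ε4).  With phased input the mapping is exact; unphased
double-heterozygotes are indeterminate and are excluded with a reported
count rather than imputed.

## 4. Interaction

The 12-cell joint stratification fits one Cox model with 11 indicators
(reference: lowest score quartile × lowest genetic group).  Multiplicative
interaction is the product-term hazard ratio.  Additive interaction uses
RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1 and AP = RERI/HR₁₁ computed from a fit with
two binaries and their product; confidence intervals are delta-method on
the coefficient covariance (gradients ∂RERI/∂β = (HR₁₁−HR₁₀, HR₁₁−HR₀₁,
HR₁₁)).  Hazard ratios proxy risk ratios here, which is standard when the
outcome is rare (~1.5% cumulative incidence).  The default dichotomies are
top score quartile vs rest and top PRS tertile vs rest (configurable).

## 5. The synthetic-cohort generator

The generator produces the data structure the analysis assumes, calibrated
to a UK-style cohort of 50–70-year-olds:

- **Exposures.**  Log-normal marginals; (µ, σ) are inverted numerically
  from target mean/IQR pairs — defaults 9.9/2.3, 14.8/3.2, 18.1/6.9,
  26.9/12.0 µg/m³ — via IQR/mean = 2 sinh(σz₀.₇₅)e^(−σ²/2).  Dependence is
  a Gaussian copula with latent Pearson r = 2 sin(πρ_s/6) matching a target
  Spearman matrix (defaults 0.78–0.95, NO2/NOx highest; rejected if not
  positive definite).
- **Covariates.**  Age truncated-normal 59.9 ± 5.4 on [50, 73]; binary and
  categorical mixes (44% male, 93% current drinkers, 85% urban, etc.) and
  normal BMI/TDI, independent of exposures by default.  An optional
  confounding knob adds a multiple of the standardized combined exposure to
  TDI, for testing that adjustment matters.
- **Genetics.**  SNP dosages Binomial(2, f_j) independently per SNP; APOE
  as two phased haplotypes drawn from (ε2, ε3, ε4) frequencies
  (0.080, 0.780, 0.140), whose Hardy–Weinberg dosage shares
  (74.0/24.1/1.96%) match the population mix the generator emulates to
  within one percentage point.
- **Outcomes.**  Exponential event times with hazard h₀·exp(lp).  The
  linear predictor combines: the score effect — linear per IQR of the true
  combined exposure (the equal-weight score, default log 1.13), or a
  quartile-step dose-response — the PRS effect (per unit, default
  log 1.25, or tertile steps), APOE dosage effects (defaults log 3.0 and
  log 8.64 for dosage 1 and 2), modest covariate effects, and an optional
  score×PRS product term (0 by default).  A useful internal consistency of
  the defaults: the linear per-IQR slope log 1.13 implies a Q4-vs-Q1
  contrast of ≈ 1.26 under the calibrated exposure distribution.
- **Censoring.**  Administrative censoring uniform over an 11.5–15.3-year
  window (median 13.4 y, SD ≈ 1.1 y, emulating staggered recruitment with
  a fixed end of follow-up), plus a 3% fraction censored uniformly early as
  a stand-in for death and loss to follow-up (the real composition of
  censoring is not part of the calibration).  Unless a baseline hazard is
  given, h₀ is solved by root-finding so the expected event fraction over
  the realized censoring times equals the target (1.5%).

Everything is driven by one integer seed; identical configuration and seed
give a bit-identical cohort.

### What the generator does not emulate

Spatially resolved exposure surfaces, address history and time-varying
exposure windows; exposure–covariate confounding (unless the knob is on);
linkage-based case ascertainment; missing data (the pipeline fails fast on
missing cells rather than imputing); population stratification or LD
structure in the genotypes.  Passing recovery tests therefore shows that
the inference machinery is correct and calibrated for data with this
structure — not that the substantive findings would replicate in any real
cohort.

## 6. Validation design and problem sizes

Exact arithmetic (score formula, IVW, HMP identities, RERI/AP) is tested
to machine precision.  Stochastic validation runs the full pipeline at
n = 25,000–50,000 with ~5–30 seeded replicates per target (the acceptance
script uses 12–30 replicates at n = 50,000–100,000), comparing
replicate-mean log-effects against the configured truths with allowances of
2% bias plus twice the Monte-Carlo standard error of the replicate mean;
HMP null calibration uses 500 replicates of n = 5,000.  The joint-cell
contrast carries a small (~4%) systematic attenuation from out-of-fold
score-quartile misclassification, so its bias allowance is 6%.

## 7. Known limitations

- The per-fold weight estimates are noisy when events are scarce
  (~75 events per held-out batch at n = 50,000); occasionally a training
  batch's weight sum approaches zero and the literal normalizer 4/Σα̂
  becomes extreme, which contaminates the pooled quartile scale for that
  replicate.  This is a property of the score formula itself at small event
  counts; it is rare at the default sizes, flagged by warnings, and
  averaged over in multi-seed summaries.
- Fixed-effect pooling and the HMP calibration assume the folds estimate a
  common effect; heterogeneous true effects across folds would require a
  random-effects extension (out of scope).
- RERI/AP inherit the rare-outcome HR≈RR approximation.
- Tie handling beyond Efron/Breslow (exact partial likelihood) is not
  implemented; synthetic event times are continuous, so ties arise only in
  degenerate inputs.
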