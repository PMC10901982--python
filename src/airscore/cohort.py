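"""Seeded synthetic cohort generator.

Exposures are log-normal with a Gaussian copula matching a target Spearman
matrix; covariates follow configurable categorical/normal marginals;
genotypes are binomial SNP dosages plus phased APOE haplotypes; event times
come from an exponential proportional-hazards model with administrative
censoring over a recruitment window and a small uniform early-censoring
fraction standing in for death and loss to follow-up.

The baseline hazard is, by default, calibrated numerically so that the
expected event fraction over the realized censoring times equals the
configured target (1.5% by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import POLLUTANTS, CohortConfig
from .genetics import HAPLOTYPE_MAP, PRSPanel, compute_prs, default_panel

_Z75 = stats.norm.ppf(0.75)


def _lognormal_params(mean: float, iqr: float) -> tuple[float, float]:
    """Invert (mean, IQR) targets to log-normal (mu, sigma).

    mean = exp(mu + sigma^2/2);  IQR = 2 exp(mu) sinh(sigma * z75), so
    IQR/mean = 2 sinh(sigma z75) exp(-sigma^2/2), monotone in sigma over the
    relevant range.
    """
    ratio = iqr / mean

    def f(s):
        return 2 * np.sinh(s * _Z75) * np.exp(-(s**2) / 2) - ratio

    sigma = optimize.brentq(f, 1e-9, 1.4)
    mu = np.log(mean) - sigma**2 / 2
    return mu, sigma


def spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Gaussian-copula conversion: latent Pearson r = 2 sin(pi rho_s / 6)."""
    return 2 * np.sin(np.pi * np.asarray(rho, float) / 6)


def generate_exposures(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the four pollutant concentrations (ug/m3)."""
    R = spearman_to_pearson(config.pollutant_spearman)
    np.fill_diagonal(R, 1.0)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "latent pollutant correlation matrix is not positive definite"
        ) from exc
    Z = rng.standard_normal((config.n_subjects, 4)) @ L.T
    cols = {}
    for j, name in enumerate(POLLUTANTS):
        mu, sigma = _lognormal_params(
            config.pollutant_means[j], config.pollutant_iqrs[j]
        )
        cols[name] = np.exp(mu + sigma * Z[:, j])
    return pd.DataFrame(cols)


def _categorical(rng, n, levels_probs: dict):
    levels = list(levels_probs)
    p = np.array([levels_probs[k] for k in levels], float)
    p = p / p.sum()
    return rng.choice(len(levels), size=n, p=p), levels


def generate_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    spec = config.covariate_spec
    n = config.n_subjects
    out = {}
    age_spec = spec["age"]
    a, b = (
        (age_spec["lo"] - age_spec["mean"]) / age_spec["sd"],
        (age_spec["hi"] - age_spec["mean"]) / age_spec["sd"],
    )
    out["age"] = stats.truncnorm.rvs(
        a, b, loc=age_spec["mean"], scale=age_spec["sd"], size=n, random_state=rng
    )
    for name in ("sex_male", "college", "income_low", "urban", "family_history"):
        out[name] = (rng.random(n) < spec[name]).astype(int)
    for name in ("bmi", "tdi"):
        out[name] = rng.normal(spec[name]["mean"], spec[name]["sd"], n)
    smoke_idx, smoke_levels = _categorical(rng, n, spec["smoking"])
    out["smoking_former"] = (np.array(smoke_levels)[smoke_idx] == "former").astype(int)
    out["smoking_current"] = (np.array(smoke_levels)[smoke_idx] == "current").astype(int)
    drink_idx, drink_levels = _categorical(rng, n, spec["drinking"])
    out["drinking_never"] = (np.array(drink_levels)[drink_idx] == "never").astype(int)
    out["drinking_former"] = (np.array(drink_levels)[drink_idx] == "former").astype(int)
    act_idx, act_levels = _categorical(rng, n, spec["activity"])
    out["activity_low"] = (np.array(act_levels)[act_idx] == "low").astype(int)
    out["activity_moderate"] = (np.array(act_levels)[act_idx] == "moderate").astype(int)
    diet_idx, diet_levels = _categorical(rng, n, spec["diet_score"])
    out["diet_score"] = np.array(diet_levels)[diet_idx].astype(int)
    return pd.DataFrame(out)


def generate_genetics(
    config: CohortConfig, rng: np.random.Generator, panel: PRSPanel | None = None
) -> pd.DataFrame:
    """SNP dosages (binomial per SNP) and phased APOE genotypes."""
    panel = panel or default_panel()
    n = config.n_subjects
    G = rng.binomial(2, panel.freqs, size=(n, len(panel.freqs)))
    out = pd.DataFrame(G, columns=panel.snp_ids)
    haps = np.array(["e2", "e3", "e4"])
    f = np.asarray(config.apoe_freqs, float)
    h1 = haps[rng.choice(3, size=n, p=f)]
    h2 = haps[rng.choice(3, size=n, p=f)]
    allele = {h: k for k, h in HAPLOTYPE_MAP.items()}  # hap -> (rs429358, rs7412)
    out["rs429358"] = [allele[a][0] + allele[b][0] for a, b in zip(h1, h2)]
    out["rs7412"] = [allele[a][1] + allele[b][1] for a, b in zip(h1, h2)]
    out["apoe_h1"] = h1
    out["apoe_h2"] = h2
    return out


def true_linear_predictor(df: pd.DataFrame, config: CohortConfig, panel: PRSPanel):
    """Centered log-hazard linear predictor of the data-generating model."""
    eff = config.true_effects
    n = len(df)
    lp = np.zeros(n)

    s_true = df[list(POLLUTANTS)].sum(axis=1).to_numpy()
    q1, q3 = np.quantile(s_true, [0.25, 0.75])
    iqr = q3 - q1
    s_std = (s_true - s_true.mean()) / iqr
    if eff.score_quartile is not None:
        cuts = np.quantile(s_true, [0.25, 0.5, 0.75])
        qidx = np.searchsorted(cuts, s_true, side="right")  # 0..3
        steps = np.array([0.0, *eff.score_quartile])
        lp += steps[qidx]
    else:
        lp += eff.score_per_iqr * s_std

    prs = compute_prs(df[panel.snp_ids].to_numpy(), panel)
    prs_c = prs - prs.mean()
    if eff.prs_group is not None:
        cuts = np.quantile(prs, [1 / 3, 2 / 3])
        gidx = np.searchsorted(cuts, prs, side="right")
        lp += np.array([0.0, *eff.prs_group])[gidx]
    else:
        lp += eff.prs_per_unit * prs_c

    dosage = ((df["apoe_h1"] == "e4").astype(int) + (df["apoe_h2"] == "e4").astype(int)).to_numpy()
    d1, d2 = eff.apoe_dosage
    lp += np.where(dosage == 1, d1, 0.0) + np.where(dosage == 2, d2, 0.0)

    for name, beta in eff.covariates.items():
        if beta:
            x = df[name].to_numpy(float)
            lp += beta * (x - x.mean())

    if eff.score_x_prs:
        lp += eff.score_x_prs * s_std * prs_c
    return lp - lp.mean()


def generate_survival(
    df: pd.DataFrame, config: CohortConfig, rng: np.random.Generator,
    panel: PRSPanel | None = None,
) -> pd.DataFrame:
    """Exponential PH event times with administrative + early censoring."""
    panel = panel or default_panel()
    n = len(df)
    lp = true_linear_predictor(df, config, panel)
    rel = np.exp(lp)

    lo, hi = config.horizon
    censor = rng.uniform(lo, hi, n) if hi > lo else np.full(n, float(hi))
    if config.early_censor_frac > 0:
        early = rng.random(n) < config.early_censor_frac
        censor = np.where(early, rng.uniform(0, censor), censor)

    if config.baseline_hazard is not None:
        h = float(config.baseline_hazard)
    else:
        target = config.event_rate

        def expected_rate(log_h):
            return np.mean(1 - np.exp(-np.exp(log_h) * rel * censor)) - target

        h = float(np.exp(optimize.brentq(expected_rate, -16, 2)))

    T = rng.exponential(1.0 / (h * rel))
    event = (T <= censor).astype(int)
    follow = np.minimum(T, censor)
    return pd.DataFrame(
        {"followup_years": follow, "event": event, "_true_lp": lp, "_baseline_hazard": h}
    )


def generate_cohort(
    config: CohortConfig, panel: PRSPanel | None = None
) -> pd.DataFrame:
    """Full participant table: one row per subject, seeded and reproducible."""
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed)
    exposures = generate_exposures(config, rng)
    covars = generate_covariates(config, rng)
    genes = generate_genetics(config, rng, panel)
    df = pd.concat([exposures, covars, genes], axis=1)
    if config.confound_exposure_tdi:
        s = df[list(POLLUTANTS)].sum(axis=1)
        df["tdi"] = df["tdi"] + config.confound_exposure_tdi * (
            (s - s.mean()) / s.std()
        )
    surv = generate_survival(df, config, rng, panel)
    df = pd.concat([df, surv.drop(columns="_baseline_hazard")], axis=1)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    df.attrs["baseline_hazard"] = float(surv["_baseline_hazard"].iloc[0])
    return df


def summarize_cohort(df: pd.DataFrame) -> dict:
    """Baseline-table style summary: marginals, person-years, follow-up, Spearman."""
    if len(df) == 0:
        raise ValueError("cannot summarize an empty cohort")
    out = {
        "n": int(len(df)),
        "person_years": float(df["followup_years"].sum()),
        "median_followup": float(df["followup_years"].median()),
        "n_events": int(df["event"].sum()),
        "event_rate": float(df["event"].mean()),
    }
    expo = {}
    degenerate = []
    for name in POLLUTANTS:
        x = df[name]
        q1, q3 = x.quantile([0.25, 0.75])
        iqr = float(q3 - q1)
        if iqr == 0:
            degenerate.append(name)
        expo[name] = {"mean": float(x.mean()), "iqr": iqr}
    out["pollutants"] = expo
    sub = df[list(POLLUTANTS)]
    if degenerate:
        out["degenerate_exposures"] = degenerate
        rho = np.full((4, 4), np.nan)
        keep = [c for c in POLLUTANTS if c not in degenerate]
        if len(keep) >= 2:
            idx = [POLLUTANTS.index(c) for c in keep]
            r = stats.spearmanr(sub[keep]).statistic
            r = np.atleast_2d(r)
            for a, ia in enumerate(idx):
                for b, ib in enumerate(idx):
                    rho[ia, ib] = r[a, b]
        np.fill_diagonal(rho, 1.0)
    else:
        rho = np.asarray(stats.spearmanr(sub).statistic)
    out["spearman"] = rho
    for name in ("age", "bmi", "tdi"):
        if name in df:
            out[name] = {"mean": float(df[name].mean()), "sd": float(df[name].std())}
    for name in ("sex_male", "college", "urban", "family_history"):
        if name in df:
            out[name] = float(df[name].mean())
    if "apoe_h1" in df:
        dosage = (df["apoe_h1"] == "e4").astype(int) + (df["apoe_h2"] == "e4").astype(int)
        out["apoe_dosage_shares"] = dosage.value_counts(normalize=True).sort_index().to_dict()
    return out
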