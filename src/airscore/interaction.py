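"""Joint exposure-genetics stratification and interaction statistics.

Subjects are cross-classified by quartile of the pollution score and a
three-level genetic risk group (PRS tertiles or APOE epsilon-4 dosage),
giving 12 strata whose hazard ratios are estimated against the low/low
reference in a single Cox fit.  Interaction is measured multiplicatively
(HR of the product term) and additively via the relative excess risk due to
interaction, RERI = HR11 - HR10 - HR01 + 1, and the attributable proportion
AP = RERI / HR11, with delta-method confidence intervals.  Hazard ratios
stand in for risk ratios here, the usual practice when the outcome is rare
(about 1.5% cumulative incidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxError
from .survival import Z95, fit_cox


@dataclass
class AdditiveInteraction:
    reri: float
    reri_ci: tuple
    ap: float
    ap_ci: tuple
    hr10: float
    hr01: float
    hr11: float


@dataclass
class InteractionResult:
    multiplicative_hr: float
    multiplicative_ci: tuple
    multiplicative_p: float
    additive: AdditiveInteraction | None = None


def joint_strata(
    df: pd.DataFrame,
    score_quartile,
    genetic_group,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
    tie_method: str = "efron",
) -> pd.DataFrame:
    """12-cell joint stratification (4 score quartiles x 3 genetic groups).

    ``score_quartile`` holds integer quartile labels 1-4 and
    ``genetic_group`` ordered labels (low < moderate/intermediate < high).
    One Cox fit with 11 indicators; reference = Q1 x low.  Returns a long
    table (quartile, genetic group, n, events, HR, CI, p).
    """
    q = np.asarray(score_quartile)
    g = pd.Categorical(genetic_group)
    if len(q) != len(df) or len(g) != len(df):
        raise ValueError("stratum labels must align with the data")
    glevels = list(g.categories)
    if len(glevels) != 3:
        raise ValueError("genetic grouping must have exactly 3 levels")
    cells = [(qq, gg) for qq in (1, 2, 3, 4) for gg in glevels]
    counts = pd.Series(
        [int(((q == qq) & (np.asarray(g) == gg)).sum()) for qq, gg in cells],
        index=pd.MultiIndex.from_tuples(cells),
    )
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"empty joint strata: {list(empty.index)}")
    ref = (q == 1) & (np.asarray(g) == glevels[0])
    if df.loc[ref, event_col].sum() < 1:
        raise CoxError("reference stratum (Q1 x low risk) has no events")

    work = df[[duration_col, event_col] + list(covariates)].copy()
    dnames = []
    for qq, gg in cells:
        if (qq, gg) == (1, glevels[0]):
            continue
        name = f"_cell_Q{qq}_{gg}"
        work[name] = ((q == qq) & (np.asarray(g) == gg)).astype(float)
        dnames.append(name)
    fit = fit_cox(work, dnames + list(covariates), duration_col, event_col,
                  tie_method=tie_method)

    rows = []
    for qq, gg in cells:
        mask = (q == qq) & (np.asarray(g) == gg)
        row = {
            "score_quartile": qq,
            "genetic_group": gg,
            "n": int(mask.sum()),
            "events": int(df.loc[mask, event_col].sum()),
        }
        if (qq, gg) == (1, glevels[0]):
            row.update(hr=1.0, ci_low=1.0, ci_high=1.0, p=np.nan)
        else:
            name = f"_cell_Q{qq}_{gg}"
            b, se = fit.params[name], fit.se[name]
            row.update(
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * se)),
                ci_high=float(np.exp(b + Z95 * se)),
                p=fit.wald_p(name),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def multiplicative_interaction(
    df: pd.DataFrame,
    score_term: str,
    genetic_term: str,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> InteractionResult:
    """HR (with CI and p) of the score x genetics product term."""
    x = df[score_term].to_numpy(float)
    z = df[genetic_term].to_numpy(float)
    prod = x * z
    for other, label in ((x, score_term), (z, genetic_term)):
        r = np.corrcoef(prod, other)[0, 1] if np.ptp(prod) > 0 and np.ptp(other) > 0 else 1.0
        if abs(r) > 0.999999:
            raise ValueError(
                f"product term is collinear with {label!r}; interaction not identifiable"
            )
    work = df[[duration_col, event_col] + list(covariates)].copy()
    work["_x"], work["_z"], work["_xz"] = x, z, prod
    fit = fit_cox(work, ["_x", "_z", "_xz"] + list(covariates), duration_col, event_col)
    b, se = fit.params["_xz"], fit.se["_xz"]
    return InteractionResult(
        multiplicative_hr=float(np.exp(b)),
        multiplicative_ci=(float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se))),
        multiplicative_p=fit.wald_p("_xz"),
    )


def reri_ap_from_fit(beta: np.ndarray, cov: np.ndarray) -> AdditiveInteraction:
    """RERI and AP with delta-method CIs from (b1, b2, b3) and their covariance.

    b1, b2 are the binary main effects, b3 the product term; HR11 =
    exp(b1+b2+b3).
    """
    beta = np.asarray(beta, float)
    cov = np.asarray(cov, float)
    if beta.shape != (3,) or cov.shape != (3, 3):
        raise ValueError("need three coefficients and their 3x3 covariance")
    if not np.isfinite(cov).all():
        raise ValueError("missing covariance for the interaction coefficients")
    hr10 = np.exp(beta[0])
    hr01 = np.exp(beta[1])
    hr11 = np.exp(beta.sum())
    reri = hr11 - hr10 - hr01 + 1
    g_reri = np.array([hr11 - hr10, hr11 - hr01, hr11])
    var_reri = float(g_reri @ cov @ g_reri)
    se_reri = np.sqrt(max(var_reri, 0.0))
    ap = reri / hr11
    # d(AP)/db_i = (dRERI/db_i - AP * dHR11/db_i) / HR11, with dHR11/db_i = HR11
    g_ap = g_reri / hr11 - ap
    var_ap = float(g_ap @ cov @ g_ap)
    se_ap = np.sqrt(max(var_ap, 0.0))
    return AdditiveInteraction(
        reri=float(reri),
        reri_ci=(float(reri - Z95 * se_reri), float(reri + Z95 * se_reri)),
        ap=float(ap),
        ap_ci=(float(ap - Z95 * se_ap), float(ap + Z95 * se_ap)),
        hr10=float(hr10),
        hr01=float(hr01),
        hr11=float(hr11),
    )


def additive_interaction(
    df: pd.DataFrame,
    exposure_high: str,
    genetics_high: str,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> AdditiveInteraction:
    """RERI/AP from a Cox fit with two binaries and their product.

    ``exposure_high`` and ``genetics_high`` are 0/1 columns (by convention
    top score quartile vs rest, and top PRS tertile or any epsilon-4 allele
    vs rest).
    """
    work = df[[duration_col, event_col] + list(covariates)].copy()
    x = df[exposure_high].to_numpy(float)
    z = df[genetics_high].to_numpy(float)
    work["_x"], work["_z"], work["_xz"] = x, z, x * z
    fit = fit_cox(work, ["_x", "_z", "_xz"] + list(covariates), duration_col, event_col)
    names = ["_x", "_z", "_xz"]
    return reri_ap_from_fit(
        fit.params[names].to_numpy(), fit.cov.loc[names, names].to_numpy()
    )
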