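"""Proportional-hazards estimation and diagnostics.

`fit_cox` maximizes the Cox partial likelihood with Efron (default) or
Breslow tie handling, returning named coefficients with their covariance.
Diagnostics cover the Grambsch-Therneau scaled-Schoenfeld test of the PH
assumption, restricted-cubic-spline dose-response modelling with a
likelihood-ratio nonlinearity test, per-IQR and quartile effect summaries
with a trend test, and Kaplan-Meier curves with the log-rank test
(via lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxError, CoxInternals, cox_newton

Z95 = stats.norm.ppf(0.975)


@dataclass
class SurvivalFit:
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    null_loglik: float
    n: int
    n_events: int
    tie_method: str
    duration_col: str
    event_col: str
    _internals: CoxInternals = field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def wald_p(self, name: str) -> float:
        z = self.params[name] / self.se[name]
        return float(2 * stats.norm.sf(abs(z)))

    def summary(self) -> pd.DataFrame:
        se = self.se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "hr": np.exp(self.params),
                "hr_ci_low": np.exp(self.params - Z95 * se),
                "hr_ci_high": np.exp(self.params + Z95 * se),
                "p": [self.wald_p(k) for k in self.params.index],
            }
        )


@dataclass
class SplineSpec:
    """Restricted cubic spline knots (3 by default, linear beyond the boundary)."""

    knot_locations: tuple

    def __post_init__(self):
        k = np.asarray(self.knot_locations, float)
        if len(k) < 3:
            raise ValueError("a restricted cubic spline needs at least 3 knots")
        if not (np.diff(k) > 0).all():
            raise ValueError("knots must be strictly increasing")
        self.knot_locations = tuple(k)

    @property
    def n_knots(self) -> int:
        return len(self.knot_locations)

    @classmethod
    def from_quantiles(cls, x, n_knots: int = 3) -> "SplineSpec":
        """Default placement at the 10th/50th/90th percentiles (3 knots)."""
        if n_knots == 3:
            qs = (0.10, 0.50, 0.90)
        else:
            qs = np.linspace(0.05, 0.95, n_knots)
        return cls(tuple(np.quantile(np.asarray(x, float), qs)))


@dataclass
class EffectEstimate:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    scale: str  # per_iqr | quartile_vs_Q1 | per_unit
    coef: float = np.nan
    se: float = np.nan

    def __post_init__(self):
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
    tie_method: str = "efron",
) -> SurvivalFit:
    """Maximum partial-likelihood Cox fit for the named covariates."""
    covariates = list(covariates)
    if not covariates:
        raise CoxError("at least one covariate is required")
    X = df[covariates].to_numpy(float)
    if np.isnan(X).any():
        raise CoxError("covariates contain missing values")
    for j, name in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise CoxError(f"covariate {name!r} is constant across subjects")
    t = df[duration_col].to_numpy(float)
    e = df[event_col].to_numpy()
    if e.sum() < 1:
        raise CoxError("no events in the data")
    beta, cov, ll, ll0, internals = cox_newton(X, t, e, ties=tie_method)
    return SurvivalFit(
        params=pd.Series(beta, index=covariates),
        cov=pd.DataFrame(cov, index=covariates, columns=covariates),
        loglik=ll,
        null_loglik=ll0,
        n=len(df),
        n_events=int(e.sum()),
        tie_method=tie_method,
        duration_col=duration_col,
        event_col=event_col,
        _internals=internals,
    )


def schoenfeld_ph_test(fit: SurvivalFit, transform: str = "rank") -> pd.DataFrame:
    """Grambsch-Therneau test of proportional hazards.

    Correlates scaled Schoenfeld residuals with a transform of event time
    ('rank', 'km'-style identity on time, or 'identity').  Returns one row
    per covariate plus a joint 'GLOBAL' row.
    """
    ints = fit._internals
    if ints is None or ints.n_events == 0:
        raise CoxError("fit carries no events to test")
    t = ints.event_times
    if transform == "rank":
        g = stats.rankdata(t, method="average")
    elif transform in ("identity", "km"):
        g = t.astype(float)
    else:
        raise ValueError(f"unknown time transform: {transform!r}")
    g = g - g.mean()
    d = ints.n_events
    resid = ints.schoenfeld  # (d, p)
    vbar = ints.mean_info  # (p, p)
    c = g @ resid  # (p,)
    denom = float(g @ g)
    rows = []
    vdiag = np.diag(vbar)
    for j, name in enumerate(fit.params.index):
        stat = c[j] ** 2 / (denom * vdiag[j])
        rows.append((name, stat, 1, float(stats.chi2.sf(stat, 1))))
    gstat = float(c @ np.linalg.solve(vbar * denom, c))
    p = len(fit.params)
    rows.append(("GLOBAL", gstat, p, float(stats.chi2.sf(gstat, p))))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"]).set_index("term")


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Restricted cubic spline basis: [x, C_1 .. C_{k-2}] (Harrell's form).

    The nonlinear columns are truncated cubics constrained to be linear
    beyond the boundary knots, normalized by the squared knot span.
    """
    x = np.asarray(x, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct values for a spline basis")
    k = np.asarray(spec.knot_locations, float)
    if k[0] < x.min() or k[-1] > x.max():
        raise ValueError("knots must lie within the range of the data")
    K = len(k)
    norm = (k[-1] - k[0]) ** 2
    cols = [x]
    for j in range(K - 2):
        tj, tk1, tk = k[j], k[-2], k[-1]
        cub = (
            np.clip(x - tj, 0, None) ** 3
            - np.clip(x - tk1, 0, None) ** 3 * (tk - tj) / (tk - tk1)
            + np.clip(x - tk, 0, None) ** 3 * (tk1 - tj) / (tk - tk1)
        )
        cols.append(cub / norm)
    return np.column_stack(cols)


def nonlinearity_test(
    df: pd.DataFrame,
    exposure: str,
    covariates: list[str],
    spec: SplineSpec | None = None,
    duration_col: str = "followup_years",
    event_col: str = "event",
) -> float:
    """LRT p-value of spline terms beyond a linear exposure effect."""
    x = df[exposure].to_numpy(float)
    spec = spec or SplineSpec.from_quantiles(x)
    basis = rcs_basis(x, spec)
    nl = basis[:, 1:]
    if np.ptp(nl, axis=0).min() == 0:
        raise CoxError("degenerate spline basis: nonlinear column is constant")
    work = df[[duration_col, event_col] + list(covariates)].copy()
    work[exposure] = x
    nl_names = [f"_rcs{j + 1}" for j in range(nl.shape[1])]
    for j, name in enumerate(nl_names):
        work[name] = nl[:, j]
    full = fit_cox(work, [exposure] + nl_names + list(covariates),
                   duration_col, event_col)
    lin = fit_cox(work, [exposure] + list(covariates), duration_col, event_col)
    lr = 2 * (full.loglik - lin.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), nl.shape[1]))


def effect_per_iqr(fit: SurvivalFit, exposure: str, iqr: float) -> EffectEstimate:
    """HR per IQR increase: exp(beta * IQR) with Wald CI on the same scale."""
    if iqr <= 0:
        raise ValueError("iqr must be positive")
    if exposure not in fit.params.index:
        raise KeyError(f"{exposure!r} not in fitted model")
    b = fit.params[exposure] * iqr
    se = fit.se[exposure] * iqr
    return EffectEstimate(
        hr=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * se)),
        ci_high=float(np.exp(b + Z95 * se)),
        p=fit.wald_p(exposure),
        scale="per_iqr",
        coef=float(b),
        se=float(se),
    )


def quartile_and_trend(
    df: pd.DataFrame,
    exposure: str,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
    cuts: np.ndarray | None = None,
):
    """Quartile-contrast HRs (Q1 reference) plus the integer-score trend test.

    Returns (list of 4 EffectEstimate, trend p-value, cut points).
    """
    x = df[exposure].to_numpy(float)
    if cuts is None:
        cuts = np.quantile(x, [0.25, 0.5, 0.75])
    cuts = np.asarray(cuts, float)
    qidx = np.searchsorted(cuts, x, side="right")  # 0..3
    sizes = np.bincount(qidx, minlength=4)
    if (sizes == 0).any():
        raise ValueError("ties in the exposure leave an empty quartile")
    work = df[[duration_col, event_col] + list(covariates)].copy()
    dnames = []
    for q in (1, 2, 3):
        name = f"_{exposure}_Q{q + 1}"
        work[name] = (qidx == q).astype(float)
        dnames.append(name)
    fit = fit_cox(work, dnames + list(covariates), duration_col, event_col)
    effects = [EffectEstimate(1.0, 1.0, 1.0, np.nan, "quartile_vs_Q1", 0.0, 0.0)]
    for name in dnames:
        b, se = fit.params[name], fit.se[name]
        effects.append(
            EffectEstimate(
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * se)),
                ci_high=float(np.exp(b + Z95 * se)),
                p=fit.wald_p(name),
                scale="quartile_vs_Q1",
                coef=float(b),
                se=float(se),
            )
        )
    work["_qtrend"] = qidx + 1.0
    tfit = fit_cox(work, ["_qtrend"] + list(covariates), duration_col, event_col)
    return effects, tfit.wald_p("_qtrend"), cuts


def km_logrank(
    df: pd.DataFrame,
    group_col: str,
    duration_col: str = "followup_years",
    event_col: str = "event",
):
    """Kaplan-Meier curves per group and the log-rank test p-value."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = df[group_col]
    levels = pd.unique(groups.dropna())
    if len(levels) < 2:
        raise ValueError("need at least two groups for a log-rank test")
    if df[event_col].sum() < 1:
        raise CoxError("no events in the data")
    curves = {}
    for lv in levels:
        sub = df[groups == lv]
        km = KaplanMeierFitter().fit(sub[duration_col], sub[event_col], label=str(lv))
        curves[lv] = km.survival_function_
    res = multivariate_logrank_test(df[duration_col], groups, df[event_col])
    return curves, float(res.p_value)
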