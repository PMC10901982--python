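"""Cox core: oracle equivalence, diagnostics, splines, effect summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from airscore import (
    SplineSpec,
    effect_per_iqr,
    fit_cox,
    km_logrank,
    nonlinearity_test,
    quartile_and_trend,
    rcs_basis,
    schoenfeld_ph_test,
)
from airscore._cox import CoxError, ConvergenceError

from conftest import two_group_exponential


def naive_partial_loglik(beta, X, t, e):
    """Written-out Efron partial likelihood by explicit risk-set enumeration."""
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for utime in sorted(set(t[e == 1])):
        D = np.where((t == utime) & (e == 1))[0]
        R = np.where(t >= utime)[0]
        m = len(D)
        wd = np.exp(X[D] @ beta).sum()
        ll += float((X[D] @ beta).sum())
        wr = np.exp(X[R] @ beta).sum()
        for r in range(m):
            ll -= np.log(wr - r / m * wd)
    return ll


TINY_INSTANCES = [
    # (x, time, event); each has an interior partial-likelihood maximum
    ([0.0, 1.0, 0.0], [1.0, 2.0, 3.0], [1, 1, 1]),
    ([0.0, 1.0, 1.0, 0.0], [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1]),
    ([2.0, 1.0, 0.0, 1.0, 0.0], [1.0, 2.0, 2.0, 3.0, 4.0], [1, 1, 1, 0, 1]),
    ([1.0, -1.0, 0.5, 0.0, 2.0], [2.0, 1.0, 4.0, 3.0, 5.0], [1, 0, 1, 1, 1]),
]


@pytest.mark.parametrize("x,t,e", TINY_INSTANCES)
def test_fit_cox_matches_grid_search_oracle(x, t, e):
    """On every tiny instance the fit equals the brute-force PL maximizer."""
    X = np.asarray(x)[:, None]
    t = np.asarray(t)
    e = np.asarray(e)
    df = pd.DataFrame({"x": x, "followup_years": t, "event": e})
    fit = fit_cox(df, ["x"])
    grid = np.arange(-5, 5, 1e-3)
    lls = np.array([naive_partial_loglik(b, X, t, e) for b in grid])
    b_oracle = grid[np.argmax(lls)]
    assert fit.params["x"] == pytest.approx(b_oracle, abs=1e-3)
    assert fit.loglik == pytest.approx(naive_partial_loglik(fit.params["x"], X, t, e), abs=1e-9)


def test_fit_cox_two_covariates_matches_numeric_oracle():
    X = np.array(
        [[0.6, 1.8], [-1.3, -0.7], [0.9, 0.0], [2.0, 0.2], [-0.6, -0.4]]
    )
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([1, 1, 0, 1, 1])
    df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "followup_years": t, "event": e})
    fit = fit_cox(df, ["a", "b"])
    res = optimize.minimize(
        lambda b: -naive_partial_loglik(b, X, t, e), x0=[0.0, 0.0], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12},
    )
    assert np.abs(fit.params.to_numpy() - res.x).max() < 1e-3


def test_two_group_exponential_recovery_and_rate_ratio_oracle():
    df = two_group_exponential(20_000, hr=2.0, seed=3)
    fit = fit_cox(df, ["x"])
    assert fit.params["x"] == pytest.approx(np.log(2), abs=0.05)
    d1 = df.loc[df.x == 1, "event"].sum()
    d0 = df.loc[df.x == 0, "event"].sum()
    e1 = df.loc[df.x == 1, "followup_years"].sum()
    e0 = df.loc[df.x == 0, "followup_years"].sum()
    oracle = np.log((d1 / e1) / (d0 / e0))
    # the partial-likelihood and parametric-rate estimators are distinct but
    # asymptotically equivalent; they agree to a few 1e-3 at this n
    assert fit.params["x"] == pytest.approx(oracle, abs=5e-3)


def test_constant_covariate_rejected():
    df = two_group_exponential(100, hr=1.0, seed=1)
    df["c"] = 3.0
    with pytest.raises(CoxError, match="'c' is constant"):
        fit_cox(df, ["x", "c"])


def test_separation_raises_convergence_error():
    # covariate perfectly orders the event times -> monotone likelihood
    n = 40
    df = pd.DataFrame(
        {
            "x": np.linspace(-2, 2, n),
            "followup_years": np.linspace(10, 1, n),
            "event": np.ones(n, int),
        }
    )
    with pytest.raises(ConvergenceError):
        fit_cox(df, ["x"])


def test_efron_and_breslow_agree_without_ties():
    df = two_group_exponential(2_000, hr=1.5, seed=5)
    fe = fit_cox(df, ["x"], tie_method="efron")
    fb = fit_cox(df, ["x"], tie_method="breslow")
    assert fe.params["x"] == pytest.approx(fb.params["x"], abs=1e-12)


def test_tied_data_matches_lifelines_efron():
    from lifelines import CoxPHFitter

    df = two_group_exponential(800, hr=1.8, seed=6)
    df["followup_years"] = np.ceil(df["followup_years"])  # force heavy ties
    fit = fit_cox(df, ["x"])
    cph = CoxPHFitter().fit(
        df[["x", "followup_years", "event"]], "followup_years", "event"
    )
    assert fit.params["x"] == pytest.approx(cph.params_["x"], abs=1e-5)
    assert fit.se["x"] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)


def test_affine_rescaling_invariance():
    df = two_group_exponential(3_000, hr=1.6, seed=7)
    df["x10"] = 10 * df["x"] + 5
    f1 = fit_cox(df, ["x"])
    f2 = fit_cox(df, ["x10"])
    assert f2.params["x10"] == pytest.approx(f1.params["x"] / 10, rel=1e-6)
    iqr1 = df["x"].quantile(0.75) - df["x"].quantile(0.25)
    iqr2 = df["x10"].quantile(0.75) - df["x10"].quantile(0.25)
    e1 = effect_per_iqr(f1, "x", iqr1)
    e2 = effect_per_iqr(f2, "x10", iqr2)
    assert e1.hr == pytest.approx(e2.hr, rel=1e-9)


def test_coefficient_recovery_is_nearly_unbiased():
    # configured scenario: single normal covariate, beta = 0.3, ~10% events
    rng = np.random.default_rng(17)
    beta = 0.3
    ests = []
    for _ in range(30):
        n = 50_000
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.008 * np.exp(beta * x)))
        C = rng.uniform(8, 15, n)
        df = pd.DataFrame(
            {"x": x, "followup_years": np.minimum(T, C), "event": (T <= C).astype(int)}
        )
        ests.append(fit_cox(df, ["x"]).params["x"])
    assert abs(np.mean(ests) - beta) < 0.02 * beta


def test_ci_coverage_is_nominal():
    rng = np.random.default_rng(23)
    beta = 0.5
    hits = 0
    reps = 500
    for _ in range(reps):
        n = 400
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.08 * np.exp(beta * x)))
        C = rng.uniform(5, 12, n)
        df = pd.DataFrame(
            {"x": x, "followup_years": np.minimum(T, C), "event": (T <= C).astype(int)}
        )
        fit = fit_cox(df, ["x"])
        lo = fit.params["x"] - 1.959964 * fit.se["x"]
        hi = fit.params["x"] + 1.959964 * fit.se["x"]
        hits += lo <= beta <= hi
    assert 0.93 <= hits / reps <= 0.97


# ---------------------------------------------------------------- Schoenfeld


def test_schoenfeld_type_one_error_is_nominal():
    rng = np.random.default_rng(31)
    rejections = 0
    reps = 500
    for _ in range(reps):
        n = 300
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.1 * np.exp(0.4 * x)))
        C = rng.uniform(3, 10, n)
        df = pd.DataFrame(
            {"x": x, "followup_years": np.minimum(T, C), "event": (T <= C).astype(int)}
        )
        fit = fit_cox(df, ["x"])
        p = schoenfeld_ph_test(fit).loc["x", "p"]
        rejections += p < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def test_schoenfeld_detects_time_increasing_effect():
    rng = np.random.default_rng(37)
    rejections = 0
    reps = 100
    for _ in range(reps):
        n = 600
        x = (rng.random(n) < 0.5).astype(float)
        # effect absent before t=3, strong after: piecewise exponential draw
        h0, h1 = 0.06, 0.06 * np.exp(1.5 * x)
        T1 = rng.exponential(1 / h0, n)
        T = np.where(T1 < 3, T1, 3 + rng.exponential(1 / h1))
        C = rng.uniform(5, 12, n)
        df = pd.DataFrame(
            {"x": x, "followup_years": np.minimum(T, C), "event": (T <= C).astype(int)}
        )
        fit = fit_cox(df, ["x"])
        rejections += schoenfeld_ph_test(fit).loc["x", "p"] < 0.05
    assert rejections / reps > 0.5


def test_schoenfeld_close_to_lifelines():
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    df = two_group_exponential(1_500, hr=1.7, seed=41)
    df["z"] = np.random.default_rng(0).standard_normal(len(df))
    fit = fit_cox(df, ["x", "z"])
    ours = schoenfeld_ph_test(fit, transform="rank")
    cph = CoxPHFitter().fit(
        df[["x", "z", "followup_years", "event"]], "followup_years", "event"
    )
    theirs = proportional_hazard_test(cph, df, time_transform="rank").summary
    for name in ("x", "z"):
        ref = theirs.loc[name, "p"]
        if hasattr(ref, "iloc"):
            ref = float(ref.iloc[0])
        assert ours.loc[name, "p"] == pytest.approx(float(ref), abs=0.02)


def test_schoenfeld_requires_fitted_covariates():
    df = two_group_exponential(100, hr=1.0, seed=2)
    with pytest.raises(CoxError):
        fit_cox(df, [])


# ----------------------------------------------------------------- Splines


def test_rcs_nonlinear_terms_vanish_below_first_knot():
    x = np.linspace(0, 10, 101)
    spec = SplineSpec((2.0, 5.0, 8.0))
    basis = rcs_basis(x, spec)
    assert basis.shape == (101, 2)  # 3 knots -> exactly 1 nonlinear column
    assert np.all(basis[x <= 2.0, 1] == 0)


def test_rcs_linear_beyond_boundary_knots():
    x = np.linspace(0, 20, 2001)
    spec = SplineSpec((2.0, 5.0, 8.0))
    basis = rcs_basis(x, spec)
    y = 1.3 * basis[:, 0] - 11.0 * basis[:, 1]  # arbitrary fitted spline
    tail = x > 8.5
    d2 = np.diff(y[tail], 2) / np.diff(x[tail])[0] ** 2
    assert np.abs(d2).max() < 1e-6


def test_rcs_requires_three_distinct_values_and_increasing_knots():
    with pytest.raises(ValueError, match="distinct"):
        rcs_basis(np.array([1.0, 1.0, 1.0, 2.0][:3]), SplineSpec((0.5, 1.0, 1.5)))
    with pytest.raises(ValueError, match="increasing"):
        SplineSpec((1.0, 1.0, 2.0))


def test_nonlinearity_test_nominal_under_linear_truth():
    rng = np.random.default_rng(43)
    rejections = 0
    reps = 300
    for _ in range(reps):
        n = 400
        x = rng.gamma(4, 1, n)
        T = rng.exponential(1 / (0.05 * np.exp(0.15 * x)))
        C = rng.uniform(3, 12, n)
        df = pd.DataFrame(
            {"x": x, "followup_years": np.minimum(T, C), "event": (T <= C).astype(int)}
        )
        rejections += nonlinearity_test(df, "x", []) < 0.05
    assert 0.02 <= rejections / reps <= 0.08


def test_nonlinearity_test_detects_saturating_dose_response():
    rng = np.random.default_rng(47)
    rejections = 0
    reps = 40
    for _ in range(reps):
        n = 800
        x = rng.gamma(4, 1, n)
        lp = 1.5 * np.minimum(x, 4.0) / 4.0  # saturating dose-response
        T = rng.exponential(1 / (0.05 * np.exp(lp)))
        C = rng.uniform(3, 12, n)
        df = pd.DataFrame(
            {"x": x, "followup_years": np.minimum(T, C), "event": (T <= C).astype(int)}
        )
        rejections += nonlinearity_test(df, "x", []) < 0.05
    assert rejections / reps > 0.5


def test_nonlinearity_degenerate_basis_errors():
    df = two_group_exponential(200, hr=1.0, seed=51)
    # binary exposure: only two distinct values, spline basis impossible
    with pytest.raises(ValueError):
        nonlinearity_test(df, "x", [])


# ------------------------------------------------- per-IQR / quartile / KM


def test_effect_per_iqr_closed_forms():
    idx = ["x"]
    fit_stub = type(
        "F",
        (),
        {
            "params": pd.Series([0.0], index=idx),
            "se": pd.Series([0.01], index=idx),
            "wald_p": lambda self, name: 1.0,
        },
    )()
    est = effect_per_iqr(fit_stub, "x", 2.3)
    assert est.hr == 1.0

    fit_stub.params = pd.Series([np.log(2) / 2.3], index=idx)
    assert effect_per_iqr(fit_stub, "x", 2.3).hr == pytest.approx(2.0, rel=1e-12)

    fit_stub.params = pd.Series([0.05], index=idx)
    fit_stub.se = pd.Series([0.01], index=idx)
    est = effect_per_iqr(fit_stub, "x", 2.3)
    assert est.hr == pytest.approx(np.exp(0.115), rel=1e-9)
    assert est.ci_low == pytest.approx(np.exp(0.0699), rel=1e-3)
    assert est.ci_high == pytest.approx(np.exp(0.1601), rel=1e-3)
    with pytest.raises(ValueError, match="iqr"):
        effect_per_iqr(fit_stub, "x", 0.0)


def test_quartiles_reference_is_one_and_cuts_are_quartiles():
    df = two_group_exponential(2_000, hr=1.0, seed=53)
    df["u"] = np.random.default_rng(1).uniform(0, 1, len(df))
    effects, p_trend, cuts = quartile_and_trend(df, "u", [])
    assert effects[0].hr == 1.0
    assert np.allclose(cuts, [0.25, 0.5, 0.75], atol=0.03)
    assert 0 < p_trend <= 1


def test_trend_test_power_under_monotone_dose_response():
    rng = np.random.default_rng(59)
    hits = 0
    reps = 100
    for _ in range(reps):
        n = 1_500
        u = rng.uniform(0, 1, n)
        T = rng.exponential(1 / (0.05 * np.exp(1.0 * u)))
        C = rng.uniform(3, 12, n)
        df = pd.DataFrame(
            {"u": u, "followup_years": np.minimum(T, C), "event": (T <= C).astype(int)}
        )
        _, p_trend, _ = quartile_and_trend(df, "u", [])
        hits += p_trend < 0.05
    assert hits / reps > 0.8


def test_quartile_ties_making_empty_bins_error():
    df = two_group_exponential(100, hr=1.0, seed=61)
    df["v"] = 1.0
    df.loc[:2, "v"] = 2.0
    with pytest.raises(ValueError, match="empty quartile"):
        quartile_and_trend(df, "v", [])


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(67)
    t = rng.exponential(5, 400)
    df = pd.DataFrame(
        {
            "followup_years": t,
            "event": np.ones(400, int),
            "g": np.repeat(["a", "b"], 200),
        }
    )
    curves, p = km_logrank(df, "g")
    sub = df[df.g == "a"]
    grid = np.quantile(sub.followup_years, [0.2, 0.5, 0.8])
    for x in grid:
        emp = (sub.followup_years > x).mean()
        km_val = curves["a"][curves["a"].index <= x].iloc[-1, 0]
        assert km_val == pytest.approx(emp, abs=1e-9)


def test_km_identical_groups_logrank_p_is_one():
    df = two_group_exponential(300, hr=1.0, seed=71).drop(columns="x")
    dup = pd.concat([df.assign(g="a"), df.assign(g="b")], ignore_index=True)
    _, p = km_logrank(dup, "g")
    assert p == pytest.approx(1.0, abs=1e-9)


def test_km_separated_exponential_groups_significant():
    df = two_group_exponential(5_000, hr=2.0, seed=73)
    df["g"] = np.where(df.x == 1, "hi", "lo")
    _, p = km_logrank(df, "g")
    assert p < 1e-6


def test_km_single_group_errors():
    df = two_group_exponential(100, hr=1.0, seed=79)
    df["g"] = "only"
    with pytest.raises(ValueError, match="two groups"):
        km_logrank(df, "g")
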