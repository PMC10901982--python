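"""End-to-end analysis runs: main bundle, subgroup re-runs, sensitivity variants.

`run_main` reproduces the full analysis sequence on a participant table:
individual-pollutant Cox estimates (per-IQR and quartiles), the
cross-validated pollution score with pooled inference, genetic-risk effects
(PRS and APOE epsilon-4 dosage), the 12-cell joint stratification, and
multiplicative/additive interaction.  Covariate sets follow the crude model
(age + sex) or the main model (plus education, BMI, drinking, smoking,
activity, diet, urban residency, deprivation, family history).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .config import MODEL1_COVARIATES, MODEL2_COVARIATES, POLLUTANTS
from .genetics import apoe_from_genotypes, compute_prs, default_panel, prs_groups
from .interaction import additive_interaction, joint_strata, multiplicative_interaction
from .score import cross_validated_score, spearman_matrix
from .survival import effect_per_iqr, fit_cox, quartile_and_trend

COVARIATE_MODELS = {
    "model1": list(MODEL1_COVARIATES),
    "model2": list(MODEL2_COVARIATES),
}


@dataclass
class AnalysisConfig:
    covariate_model: str = "model2"
    k_folds: int = 10
    seed: int = 0
    weight_mode: str = "single"
    prs_scheme: str = "tertile"
    age_range: tuple | None = None
    min_followup: float = 0.0
    extra_covariates: tuple = ()
    subgroups: tuple = (
        "sex", "age", "income", "education", "tdi", "smoking",
        "drinking", "activity", "diet", "bmi", "urban",
    )
    sensitivity_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.covariate_model not in COVARIATE_MODELS:
            raise ValueError(f"unknown covariate model: {self.covariate_model!r}")
        flags = self.sensitivity_flags
        if flags.get("include_age_lt_50") and flags.get("restrict_age_ge_60"):
            raise ValueError(
                "contradictory sensitivity flags: include_age_lt_50 and restrict_age_ge_60"
            )

    @property
    def covariates(self) -> list[str]:
        return COVARIATE_MODELS[self.covariate_model] + list(self.extra_covariates)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def prepare_cohort(df: pd.DataFrame, panel=None) -> pd.DataFrame:
    """Attach PRS and APOE columns; fail fast on missing cells."""
    panel = panel or default_panel()
    df = df.copy()
    core = [c for c in df.columns if not c.startswith("_")]
    if df[core].isna().any().any():
        bad = df[core].columns[df[core].isna().any()].tolist()
        raise ValueError(f"cohort contains missing values in: {bad}")
    if "prs" not in df:
        df["prs"] = compute_prs(df[panel.snp_ids].to_numpy(), panel)
    if "apoe_dosage" not in df:
        phased = "apoe_h1" in df
        apoe = apoe_from_genotypes(df["rs429358"], df["rs7412"], phased=phased)
        df["apoe_dosage"] = apoe["apoe_dosage"].to_numpy()
        df["apoe_group"] = apoe["apoe_group"].to_numpy()
        if not apoe["valid"].all():
            df = df.loc[apoe["valid"].to_numpy()].copy()
    return df


def _apply_population_filters(df: pd.DataFrame, config: AnalysisConfig):
    log = {}
    if config.age_range is not None:
        lo, hi = config.age_range
        keep = (df["age"] >= lo) & (df["age"] < hi)
        log["excluded_age"] = int((~keep).sum())
        df = df.loc[keep]
    if config.min_followup > 0:
        keep = df["followup_years"] >= config.min_followup
        log["excluded_short_followup"] = int((~keep).sum())
        df = df.loc[keep]
    return df.reset_index(drop=True), log


def _individual_pollutants(df, covariates):
    rows = []
    for pol in POLLUTANTS:
        iqr = float(df[pol].quantile(0.75) - df[pol].quantile(0.25))
        fit = fit_cox(df, [pol] + covariates)
        est = effect_per_iqr(fit, pol, iqr)
        effects, trend_p, _ = quartile_and_trend(df, pol, covariates)
        rows.append(
            {
                "pollutant": pol,
                "iqr": iqr,
                "hr_per_iqr": est.hr,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
                **{
                    f"hr_Q{q + 1}": effects[q].hr for q in range(4)
                },
                "p_trend": trend_p,
            }
        )
    return pd.DataFrame(rows)


def _genetics_effects(df, covariates, scheme):
    out = {}
    fit = fit_cox(df, ["prs"] + covariates)
    est = df["prs"]
    prs_sum = fit.summary().loc["prs"]
    out["prs_per_unit"] = prs_sum.to_dict()
    groups = prs_groups(est, scheme=scheme)
    df = df.copy()
    df["_prs_mod"] = (np.asarray(groups) == "moderate").astype(float)
    df["_prs_high"] = (np.asarray(groups) == "high").astype(float)
    gfit = fit_cox(df, ["_prs_mod", "_prs_high"] + covariates)
    out["prs_groups"] = gfit.summary().loc[["_prs_mod", "_prs_high"]]
    df["_apoe1"] = (df["apoe_dosage"] == 1).astype(float)
    df["_apoe2"] = (df["apoe_dosage"] == 2).astype(float)
    afit = fit_cox(df, ["_apoe1", "_apoe2"] + covariates)
    out["apoe_dosage"] = afit.summary().loc[["_apoe1", "_apoe2"]]
    return out, groups


def run_main(df: pd.DataFrame, config: AnalysisConfig, panel=None) -> dict:
    """Full results bundle; deterministic given cohort + config."""
    panel = panel or default_panel()
    df = prepare_cohort(df, panel)
    df, filter_log = _apply_population_filters(df, config)
    covars = config.covariates

    bundle: dict = {
        "meta": {
            "n": int(len(df)),
            "n_events": int(df["event"].sum()),
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
            "covariate_model": config.covariate_model,
            **filter_log,
        }
    }
    bundle["spearman"] = spearman_matrix(df)
    bundle["individual"] = _individual_pollutants(df, covars)

    cv = cross_validated_score(
        df, covars, k=config.k_folds, seed=config.seed,
        weight_mode=config.weight_mode,
    )
    bundle["score"] = cv
    df = df.copy()
    df["score"] = cv.oof_score.to_numpy()
    df["score_q"] = np.searchsorted(cv.cuts, df["score"].to_numpy(), side="right") + 1

    genetics, prs_group_labels = _genetics_effects(df, covars, config.prs_scheme)
    bundle["genetics"] = genetics
    df["prs_group"] = prs_group_labels

    apoe_group = pd.Categorical(
        np.array(["low", "intermediate", "high"])[df["apoe_dosage"].astype(int)],
        categories=["low", "intermediate", "high"],
        ordered=True,
    )
    bundle["joint_prs"] = joint_strata(df, df["score_q"], df["prs_group"], covars)
    bundle["joint_apoe"] = joint_strata(df, df["score_q"], apoe_group, covars)

    df["_score_iqr_units"] = df["score"] / cv.iqr
    mult = multiplicative_interaction(df, "_score_iqr_units", "prs", covars)
    df["_score_high"] = (df["score_q"] == 4).astype(float)
    df["_prs_high"] = (np.asarray(df["prs_group"]) == "high").astype(float)
    add = additive_interaction(df, "_score_high", "_prs_high", covars)
    bundle["interaction"] = {"multiplicative": mult, "additive": add}
    return bundle


_SUBGROUP_RULES = {
    "sex": lambda d: np.where(d["sex_male"] == 1, "male", "female"),
    "age": lambda d: np.where(d["age"] < 60, "lt60", "ge60"),
    "income": lambda d: np.where(d["income_low"] == 1, "low", "high"),
    "education": lambda d: np.where(d["college"] == 1, "college", "no_college"),
    "tdi": lambda d: np.where(d["tdi"] < d["tdi"].mean(), "low_tdi", "high_tdi"),
    "smoking": lambda d: np.select(
        [d["smoking_former"] == 1, (d["smoking_former"] == 0) & (d["smoking_current"] == 0)],
        ["former", "never"], default="__drop__"),
    "drinking": lambda d: np.select(
        [d["drinking_former"] == 1, d["drinking_never"] == 1],
        ["former", "never"], default="__drop__"),
    "activity": lambda d: np.select(
        [d["activity_low"] == 1, d["activity_moderate"] == 1],
        ["low", "moderate"], default="high"),
    "diet": lambda d: np.where(d["diet_score"] <= 2, "0-2", "3-5"),
    "bmi": lambda d: np.select(
        [d["bmi"] < 25, d["bmi"] < 30], ["lt25", "25-30"], default="ge30"),
    "urban": lambda d: np.where(d["urban"] == 1, "urban", "rural"),
}


def run_subgroups(df: pd.DataFrame, config: AnalysisConfig, panel=None) -> pd.DataFrame:
    """Score pipeline re-run within each stratum of each requested stratifier."""
    panel = panel or default_panel()
    df = prepare_cohort(df, panel)
    df, _ = _apply_population_filters(df, config)
    covars = config.covariates
    rows = []
    for name in config.subgroups:
        if name not in _SUBGROUP_RULES:
            raise ValueError(f"unknown stratifier: {name!r}")
        labels = pd.Series(_SUBGROUP_RULES[name](df), index=df.index)
        levels = [lv for lv in pd.unique(labels) if lv != "__drop__"]
        if len(levels) < 2:
            raise ValueError(f"stratifier {name!r} has a single level in these data")
        for lv in levels:
            sub = df.loc[labels == lv].reset_index(drop=True)
            if sub["event"].sum() < config.k_folds:
                warnings.warn(
                    f"subgroup {name}={lv}: too few events; skipped", stacklevel=2
                )
                continue
            strat_covars = [
                c for c in covars
                if np.ptp(sub[c].to_numpy(float)) > 0
            ]
            cv = cross_validated_score(
                sub, strat_covars, k=config.k_folds, seed=config.seed,
                weight_mode=config.weight_mode, quartiles=False,
            )
            rows.append(
                {
                    "stratifier": name,
                    "level": lv,
                    "n": len(sub),
                    "events": int(sub["event"].sum()),
                    "hr_per_iqr": cv.pooled.hr,
                    "ci_low": cv.pooled.ci_low,
                    "ci_high": cv.pooled.ci_high,
                    "p_calibrated": cv.pooled.p_calibrated,
                }
            )
    return pd.DataFrame(rows)


def run_sensitivity(df: pd.DataFrame, config: AnalysisConfig, panel=None) -> dict:
    """Labelled variants of the main score analysis per sensitivity flag."""
    flags = config.sensitivity_flags
    known = {
        "prs_quintile_scheme", "drop_followup_lt_2y",
        "include_age_lt_50", "restrict_age_ge_60", "extra_covariates",
    }
    unknown = set(flags) - known
    if unknown:
        raise ValueError(f"unknown sensitivity flags: {sorted(unknown)}")
    variants = {}
    if flags.get("prs_quintile_scheme"):
        variants["prs_quintile_scheme"] = replace(
            config, prs_scheme="quintile_1_234_5", sensitivity_flags={}
        )
    if flags.get("drop_followup_lt_2y"):
        variants["drop_followup_lt_2y"] = replace(
            config, min_followup=2.0, sensitivity_flags={}
        )
    if flags.get("include_age_lt_50"):
        variants["include_age_lt_50"] = replace(
            config, age_range=None, sensitivity_flags={}
        )
    if flags.get("restrict_age_ge_60"):
        variants["restrict_age_ge_60"] = replace(
            config, age_range=(60.0, np.inf), sensitivity_flags={}
        )
    if flags.get("extra_covariates"):
        variants["extra_covariates"] = replace(
            config, extra_covariates=tuple(flags["extra_covariates"]),
            sensitivity_flags={},
        )
    out = {}
    for label, cfg in variants.items():
        out[label] = run_main(df, cfg, panel)
    return out


def save_bundle(bundle: dict, outdir) -> None:
    """Write the results bundle as delimited tables plus a JSON manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    def _write(name, frame):
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=True)
        written[name] = path.name

    _write("spearman", bundle["spearman"])
    _write("individual_pollutants", bundle["individual"].set_index("pollutant"))
    cv = bundle["score"]
    _write("score_per_fold", cv.per_fold_table().set_index("fold"))
    _write("score_pooled", cv.pooled_table().set_index("term"))
    gen = bundle["genetics"]
    _write("genetics_prs_groups", gen["prs_groups"])
    _write("genetics_apoe", gen["apoe_dosage"])
    _write("joint_strata_prs", bundle["joint_prs"].set_index(["score_quartile", "genetic_group"]))
    _write("joint_strata_apoe", bundle["joint_apoe"].set_index(["score_quartile", "genetic_group"]))
    inter = bundle["interaction"]
    add = inter["additive"]
    inter_tab = pd.DataFrame(
        [
            {
                "measure": "multiplicative_hr",
                "estimate": inter["multiplicative"].multiplicative_hr,
                "ci_low": inter["multiplicative"].multiplicative_ci[0],
                "ci_high": inter["multiplicative"].multiplicative_ci[1],
                "p": inter["multiplicative"].multiplicative_p,
            },
            {
                "measure": "reri",
                "estimate": add.reri,
                "ci_low": add.reri_ci[0],
                "ci_high": add.reri_ci[1],
                "p": np.nan,
            },
            {
                "measure": "ap",
                "estimate": add.ap,
                "ci_low": add.ap_ci[0],
                "ci_high": add.ap_ci[1],
                "p": np.nan,
            },
        ]
    ).set_index("measure")
    _write("interaction", inter_tab)
    manifest = {**bundle["meta"], "tables": written,
                "pooled_hr_per_iqr": cv.pooled.hr,
                "pooled_p_calibrated": cv.pooled.p_calibrated}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
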