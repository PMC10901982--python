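"""Polygenic risk score and APOE epsilon-4 genotype handling.

The PRS is a weighted sum of risk-allele dosages over a 29-SNP panel,
PRS_i = sum_j G_ij * beta_j with G_ij in {0, 1, 2}.  APOE genotypes are
derived from the rs429358/rs7412 coding variants: the epsilon-4 haplotype
carries C at both sites, epsilon-3 is (T, C) and epsilon-2 is (T, T);
subjects are grouped by their epsilon-4 dosage (0 = low, 1 = intermediate,
2 = high risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_PANEL_SNPS = 29

APOE_GROUP_BY_DOSAGE = {0: "low", 1: "intermediate", 2: "high"}

#: haplotype defined by (rs429358 allele, rs7412 allele)
HAPLOTYPE_MAP = {("C", "C"): "e4", ("T", "C"): "e3", ("T", "T"): "e2", ("C", "T"): "e1"}


@dataclass
class PRSPanel:
    """A 29-SNP risk panel: identifiers, risk alleles, frequencies, weights."""

    table: pd.DataFrame  # columns: snp_id, risk_allele, freq, weight

    def __post_init__(self):
        required = {"snp_id", "risk_allele", "freq", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        if len(self.table) != N_PANEL_SNPS:
            raise ValueError(
                f"panel must contain exactly {N_PANEL_SNPS} SNPs, got {len(self.table)}"
            )
        f = self.table["freq"].to_numpy(float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        if not np.isfinite(self.table["weight"].to_numpy(float)).all():
            raise ValueError("panel weights must be finite")

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    @property
    def freqs(self) -> np.ndarray:
        return self.table["freq"].to_numpy(float)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PRSPanel":
        return cls(pd.read_csv(path, sep="\t"))


def default_panel() -> PRSPanel:
    """Bundled synthetic panel: 29 placeholder SNPs with unit-variance PRS.

    Frequencies span the common range (0.08-0.45) and weights are scaled so
    that the population PRS variance sum(w_j^2 * 2 f_j (1 - f_j)) equals 1,
    i.e. the PRS is on an SD-unit scale.  Real GWAS weights can be supplied
    as a TSV with the same columns instead.
    """
    j = np.arange(N_PANEL_SNPS)
    freqs = 0.08 + 0.37 * (j % 10) / 9.0
    raw = 1.0 + 0.8 * np.cos(1.0 + 2.3 * j)  # fixed, positive, varied weights
    var = np.sum(raw**2 * 2 * freqs * (1 - freqs))
    w = raw / np.sqrt(var)
    table = pd.DataFrame(
        {
            "snp_id": [f"snp_sim_{i + 1:02d}" for i in j],
            "risk_allele": ["A"] * N_PANEL_SNPS,
            "freq": freqs,
            "weight": w,
        }
    )
    return PRSPanel(table)


def compute_prs(dosages, panel: PRSPanel) -> np.ndarray:
    """Weighted dosage sum; accepts one (29,) vector or an (n, 29) matrix."""
    G = np.asarray(dosages)
    single = G.ndim == 1
    if single:
        G = G[None, :]
    if G.shape[1] != N_PANEL_SNPS:
        raise ValueError(
            f"expected {N_PANEL_SNPS} dosages per subject, got {G.shape[1]}"
        )
    if not np.isin(G, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    prs = G.astype(float) @ panel.weights
    return float(prs[0]) if single else prs


def prs_groups(prs_values, scheme: str = "tertile") -> pd.Categorical:
    """Label subjects low/moderate/high by PRS quantiles.

    'tertile' splits at the 1/3 and 2/3 quantiles (equal thirds); the
    'quintile_1_234_5' sensitivity scheme uses a 20/60/20 split.  Cuts are
    value-based, so tied values always share a label (heavy ties may unbalance
    group sizes; a warning is emitted).
    """
    x = np.asarray(prs_values, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct PRS values to form groups")
    if scheme == "tertile":
        qs = (1 / 3, 2 / 3)
    elif scheme == "quintile_1_234_5":
        qs = (0.2, 0.8)
    else:
        raise ValueError(f"unknown grouping scheme: {scheme!r}")
    lo_cut, hi_cut = np.quantile(x, qs)
    labels = np.where(x <= lo_cut, "low", np.where(x <= hi_cut, "moderate", "high"))
    sizes = pd.Series(labels).value_counts()
    expected = np.array([qs[0], qs[1] - qs[0], 1 - qs[1]]) * len(x)
    realized = sizes.reindex(["low", "moderate", "high"]).fillna(0).to_numpy(float)
    if np.abs(realized - expected).max() > max(2.0, 0.05 * len(x)):
        warnings.warn(
            "heavy ties at a PRS group boundary produced unbalanced groups",
            stacklevel=2,
        )
    return pd.Categorical(labels, categories=["low", "moderate", "high"], ordered=True)


def apoe_from_genotypes(rs429358, rs7412, phased: bool = True) -> pd.DataFrame:
    """Epsilon-4 dosage and risk group from the two APOE coding variants.

    Genotypes are two-character strings over {C, T} per subject.  When
    ``phased`` the i-th characters of the two strings form haplotype i; the
    epsilon-4 dosage is the number of (C, C) haplotypes.  Unphased subjects
    heterozygous at both sites are indeterminate: they are flagged invalid
    (``valid`` False, dosage/group missing) and a warning reports the count.
    """
    a = pd.Series(rs429358).astype(str).str.upper()
    b = pd.Series(rs7412).astype(str).str.upper()
    if not a.str.fullmatch("[CT]{2}").all() or not b.str.fullmatch("[CT]{2}").all():
        raise ValueError("genotypes must be two-letter strings over {C, T}")
    n = len(a)
    dosage = np.zeros(n, float)
    valid = np.ones(n, bool)
    if phased:
        for hap in (0, 1):
            dosage += (
                (a.str[hap] == "C") & (b.str[hap] == "C")
            ).to_numpy(int)
    else:
        a_sorted = a.apply(lambda g: "".join(sorted(g)))
        b_sorted = b.apply(lambda g: "".join(sorted(g)))
        ambiguous = (a_sorted == "CT") & (b_sorted == "CT")
        valid &= ~ambiguous.to_numpy()
        if ambiguous.any():
            warnings.warn(
                f"{int(ambiguous.sum())} unphased double-heterozygote APOE "
                "diplotypes are indeterminate and were excluded",
                stacklevel=2,
            )
        # without ambiguity the diplotype determines the haplotypes uniquely
        n_c_a = a_sorted.str.count("C").to_numpy()
        n_c_b = b_sorted.str.count("C").to_numpy()
        # epsilon-4 count = number of haplotypes with C at both sites
        dosage = np.minimum(n_c_a, n_c_b).astype(float)
        dosage[~valid] = np.nan
    group = pd.Series(
        [APOE_GROUP_BY_DOSAGE.get(d) if np.isfinite(d) else None
         for d in dosage]
    )
    out = pd.DataFrame(
        {
            "apoe_dosage": dosage,
            "apoe_group": pd.Categorical(
                group, categories=["low", "intermediate", "high"], ordered=True
            ),
            "valid": valid,
        }
    )
    return out
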