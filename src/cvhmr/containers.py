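"""Shared data containers for genotype data, summary statistics and MR results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf"]

#: Columns of a per-SNP association/summary-statistics table.
SUMMARY_COLUMNS = ["snp", "a1", "a2", "eaf", "beta", "se", "p", "n"]

_BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) plus per-SNP metadata.

    Dosages count copies of the A1 (effect/minor) allele and live in
    ``{0, 1, 2}``; missing entries are ``NaN``, never zero-coded.
    ``snps`` has columns snp, chrom, pos, a1, a2, maf.
    """

    dosage: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D individuals x SNPs array")
        if self.dosage.shape[1] != len(self.snps):
            raise ValueError(
                f"dosage has {self.dosage.shape[1]} SNP columns but metadata "
                f"describes {len(self.snps)} SNPs"
            )
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snp metadata missing columns: {missing}")
        if self.snps["snp"].duplicated().any():
            dup = self.snps.loc[self.snps["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate SNP id: {dup!r}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def observed_maf(self) -> np.ndarray:
        """Minor-allele (A1) frequency recomputed from the dosages."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return freq

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def subset(self, mask_or_ids) -> "GenotypeMatrix":
        """Column subset by boolean mask or by an iterable of SNP ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = list(mask_or_ids)
            lookup = {s: i for i, s in enumerate(self.snps["snp"])}
            absent = [s for s in wanted if s not in lookup]
            if absent:
                raise KeyError(f"SNPs not in genotype matrix: {absent}")
            idx = np.array([lookup[s] for s in wanted], dtype=int)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
        )

    def column(self, snp_id: str) -> np.ndarray:
        pos = self.snps.index[self.snps["snp"] == snp_id]
        if len(pos) == 0:
            raise KeyError(f"SNP not in genotype matrix: {snp_id!r}")
        return self.dosage[:, pos[0]]


def validate_summary_stats(df: pd.DataFrame, allow_indels: bool = False) -> pd.DataFrame:
    """Validate a per-SNP summary-statistics table.

    Requires columns snp, a1, a2, eaf, beta, se, p, n; rejects duplicate ids,
    non-positive SEs and (unless ``allow_indels``) non-single-base alleles.
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ValueError(f"duplicate SNP id in summary statistics: {dup!r}")
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, "snp"].iloc[0]
        raise ValueError(f"non-positive SE for SNP {bad!r}")
    if not allow_indels:
        ok = df["a1"].isin(_BASES) & df["a2"].isin(_BASES)
        if not ok.all():
            bad = df.loc[~ok, "snp"].iloc[0]
            raise ValueError(f"non-single-base alleles for SNP {bad!r}")
    return df.reset_index(drop=True)


@dataclass
class MrResult:
    """Causal-estimate record shared by every MR estimator.

    ``beta`` is in outcome units per exposure unit; ``ci_low``/``ci_high``
    bound the 95% confidence interval; ``n`` is the sample size (one-sample
    methods) or the number of instrument SNPs (summary-data methods).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
        }
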