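"""Genotype QC, per-SNP association scans and LD clumping.

The scan fits, for each SNP separately, an ordinary least-squares model of
the phenotype on allele dosage plus covariates (additive allelic effects),
reporting the dosage coefficient with its SE and two-sided t-test p-value.
Missing dosages are dropped per SNP (complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix


@dataclass(frozen=True)
class ClumpSpec:
    """Thresholds for greedy LD clumping of an association scan."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


def hwe_exact_test(n_aa_major: int, n_het: int, n_aa_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration (the standard exact formulation used
    with genome-wide thresholds such as 5.7E-7).
    """
    counts = (n_aa_major, n_het, n_aa_minor)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype observation required")

    from scipy.special import gammaln

    n_rare = 2 * min(n_aa_major, n_aa_minor) + n_het
    # heterozygote count shares the parity of the rare-allele count; log-space
    # conditional probabilities given the allele counts (constant terms cancel
    # after normalization)
    h = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - h) // 2
    common_hom = n - h - rare_hom
    ok = common_hom >= 0
    het_values, rare_hom, common_hom = h[ok], rare_hom[ok], common_hom[ok]
    logp = (
        -gammaln(common_hom + 1)
        - gammaln(het_values + 1)
        - gammaln(rare_hom + 1)
        + het_values * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()

    p_obs = probs[het_values == n_het][0]
    # tolerance guards against ties lost to rounding
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts (major hom, het, minor hom) from dosages."""
    g = np.rint(dosage[~np.isnan(dosage)]).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 5.7e-7,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs failing call-rate, HWE or MAF filters.

    A SNP survives iff call rate >= ``call_rate_min``, HWE exact p
    >= ``hwe_p_min`` and observed MAF strictly greater than ``maf_min``.
    Returns the filtered matrix and an exclusion log with one row per
    dropped SNP naming the first failed filter.
    """
    keep = np.ones(g.n_snps, dtype=bool)
    log_rows = []
    call_rates = g.call_rate()
    mafs = g.observed_maf()
    for j in range(g.n_snps):
        snp = g.snps.loc[j, "snp"]
        if call_rates[j] < call_rate_min:
            keep[j] = False
            log_rows.append({"snp": snp, "reason": "call_rate", "value": call_rates[j]})
            continue
        p_hwe = hwe_exact_test(*genotype_counts(g.dosage[:, j]))
        if p_hwe < hwe_p_min:
            keep[j] = False
            log_rows.append({"snp": snp, "reason": "hwe", "value": p_hwe})
            continue
        maf = min(mafs[j], 1.0 - mafs[j])
        if not maf > maf_min:
            keep[j] = False
            log_rows.append({"snp": snp, "reason": "maf", "value": maf})
    log = pd.DataFrame(log_rows, columns=["snp", "reason", "value"])
    return g.subset(keep), log


def _ols_last_coef(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """beta, se, two-sided p for the last column of X in an OLS fit."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = y - X @ beta
    df = n - k
    if df <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    if se == 0:
        p = 0.0
    else:
        t = beta[-1] / se
        p = float(2 * stats.t.sf(abs(t), df))
    return float(beta[-1]), se, p, n


def assoc_scan(
    g: GenotypeMatrix,
    phenotype,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP additive OLS association scan with covariate adjustment.

    Returns a table with columns chrom, snp, a1, a2, maf, pos, beta, se, p,
    n_used, flag (``"ok"`` or ``"constant"`` for SNPs degenerate after
    missing-data removal).
    """
    y_all = np.asarray(phenotype, dtype=float)
    if y_all.shape[0] != g.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    if covariates is not None:
        C_all = np.asarray(covariates, dtype=float)
        if C_all.shape[0] != g.n_individuals:
            raise ValueError("covariate rows do not match genotype rows")
    else:
        C_all = np.empty((g.n_individuals, 0))

    mafs = g.observed_maf()
    rows = []
    for j in range(g.n_snps):
        dose = g.dosage[:, j]
        ok = ~np.isnan(dose) & ~np.isnan(y_all)
        d, y, C = dose[ok], y_all[ok], C_all[ok]
        meta = g.snps.loc[j]
        row = {
            "chrom": meta["chrom"], "snp": meta["snp"], "a1": meta["a1"],
            "a2": meta["a2"], "maf": min(mafs[j], 1 - mafs[j]), "pos": meta["pos"],
        }
        if d.size < C.shape[1] + 3 or np.ptp(d) == 0:
            row.update(beta=np.nan, se=np.nan, p=np.nan, n_used=int(d.size), flag="constant")
        else:
            X = np.column_stack([np.ones(d.size), C, d])
            beta, se, p, n = _ols_last_coef(X, y)
            row.update(beta=beta, se=se, p=p, n_used=n, flag="ok")
        rows.append(row)
    return pd.DataFrame(rows)


def ld_r2(g_a, g_b) -> float:
    """Squared Pearson correlation of two dosage vectors (composite r^2).

    Pairs with a missing value in either vector are dropped; constant
    vectors after removal are rejected.
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(assoc: pd.DataFrame, g: GenotypeMatrix, spec: ClumpSpec = ClumpSpec()) -> list[str]:
    """Greedy LD clumping: return index-SNP ids sorted by (chrom, pos).

    Repeatedly takes the smallest-p unclaimed SNP below ``p_threshold`` as an
    index and claims every unclaimed SNP on the same chromosome within
    ``window_kb`` with r^2 >= ``r2_threshold`` to it.  Ties on p are broken
    by (chrom, pos, id).
    """
    table = assoc.merge(g.snps[["snp"]], on="snp")
    if len(table) != len(assoc):
        raise ValueError("association table contains SNPs absent from the genotype matrix")
    cand = table[table["p"] < spec.p_threshold].copy()
    cand = cand.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")

    claimed: set[str] = set()
    indices: list[tuple] = []
    window_bp = spec.window_kb * 1000.0
    for _, row in cand.iterrows():
        if row["snp"] in claimed:
            continue
        claimed.add(row["snp"])
        indices.append((row["chrom"], row["pos"], row["snp"]))
        idx_dose = g.column(row["snp"])
        same_chr = table[(table["chrom"] == row["chrom"]) & ~table["snp"].isin(claimed)]
        near = same_chr[(same_chr["pos"] - row["pos"]).abs() <= window_bp]
        for _, other in near.iterrows():
            try:
                r2 = ld_r2(idx_dose, g.column(other["snp"]))
            except ValueError:
                continue
            if r2 >= spec.r2_threshold:
                claimed.add(other["snp"])
    indices.sort(key=lambda t: (t[0], t[1], t[2]))
    return [snp for _, _, snp in indices]
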