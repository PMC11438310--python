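"""Multivariable Mendelian randomization.

Regresses outcome SNP effects jointly on the effects of several exposures
(weighted least squares, no intercept, weights ``se_y^-2``), so each
coefficient is the direct causal effect of one exposure conditional on the
others — e.g. a lifestyle factor's effect on epigenetic age acceleration
adjusted for BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MrResult, validate_summary_stats
from .gwas import ClumpSpec, clump
from .twosample import harmonize


@dataclass
class MvInstrumentSet:
    """Joint instruments for several exposures against one outcome.

    ``bx`` is a SNP x exposures effect matrix with SEs in ``se_x``; outcome
    effects are aligned to the same allele orientation per SNP.
    """

    snps: list[str]
    exposures: list[str]
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    log: pd.DataFrame = field(default_factory=pd.DataFrame)


def mv_instruments(
    exposure_stats: list[pd.DataFrame],
    outcome_stats: pd.DataFrame,
    ld_reference: GenotypeMatrix,
    p_threshold: float = 5e-8,
    clump_spec: ClumpSpec = ClumpSpec(),
    exposure_names: list[str] | None = None,
) -> MvInstrumentSet:
    """Select and harmonize instruments for a multivariable model.

    Takes the union of SNPs genome-wide significant for any exposure,
    clumps it against ``ld_reference`` using the smallest per-SNP p across
    exposures, then harmonizes every exposure and the outcome to the first
    exposure's allele orientation.  SNPs absent from any table are dropped
    with a logged reason.
    """
    if len(exposure_stats) < 2:
        raise ValueError("multivariable MR needs at least 2 exposures")
    names = exposure_names or [f"exposure{i + 1}" for i in range(len(exposure_stats))]
    stats_list = [validate_summary_stats(s) for s in exposure_stats]
    outcome_stats = validate_summary_stats(outcome_stats)

    sig: set[str] = set()
    for s in stats_list:
        sig |= set(s.loc[s["p"] < p_threshold, "snp"])
    log_rows = []
    present = sig
    for s, name in zip(stats_list, names):
        missing = present - set(s["snp"])
        for snp in sorted(missing):
            log_rows.append({"snp": snp, "reason": f"absent_in_{name}"})
        present = present - missing
    missing = present - set(outcome_stats["snp"])
    for snp in sorted(missing):
        log_rows.append({"snp": snp, "reason": "absent_in_outcome"})
    present -= missing
    missing = present - set(ld_reference.snps["snp"])
    for snp in sorted(missing):
        log_rows.append({"snp": snp, "reason": "absent_in_ld_reference"})
    present -= missing
    if not present:
        raise ValueError("no usable instrument SNPs across all tables")

    # min-p across exposures drives the clumping priority
    min_p = pd.concat(
        [s.set_index("snp").loc[sorted(present), "p"] for s in stats_list], axis=1
    ).min(axis=1)
    ref = ld_reference.subset(sorted(present))
    assoc = ref.snps[["snp", "chrom", "pos"]].copy()
    assoc["p"] = min_p.loc[assoc["snp"]].to_numpy()
    kept = clump(assoc, ref, ClumpSpec(p_threshold=1.0,
                                       r2_threshold=clump_spec.r2_threshold,
                                       window_kb=clump_spec.window_kb))

    anchor = stats_list[0][stats_list[0]["snp"].isin(kept)].reset_index(drop=True)
    bx_cols, se_cols = [anchor.set_index("snp")["beta"]], [anchor.set_index("snp")["se"]]
    usable = set(kept)
    for s, name in zip(stats_list[1:], names[1:]):
        h = harmonize(anchor, s)
        dropped = usable - set(h.table["snp"])
        for snp in sorted(dropped):
            log_rows.append({"snp": snp, "reason": f"unharmonizable_in_{name}"})
        usable &= set(h.table["snp"])
        bx_cols.append(h.table.set_index("snp")["by"])
        se_cols.append(h.table.set_index("snp")["se_y"])
    h_out = harmonize(anchor, outcome_stats)
    dropped = usable - set(h_out.table["snp"])
    for snp in sorted(dropped):
        log_rows.append({"snp": snp, "reason": "unharmonizable_in_outcome"})
    usable &= set(h_out.table["snp"])
    if not usable:
        raise ValueError("no instrument SNPs survived harmonization")

    order = [s for s in kept if s in usable]
    bx = np.column_stack([c.loc[order].to_numpy(dtype=float) for c in bx_cols])
    se_x = np.column_stack([c.loc[order].to_numpy(dtype=float) for c in se_cols])
    out = h_out.table.set_index("snp").loc[order]
    return MvInstrumentSet(
        snps=order, exposures=names, bx=bx, se_x=se_x,
        by=out["by"].to_numpy(dtype=float), se_y=out["se_y"].to_numpy(dtype=float),
        log=pd.DataFrame(log_rows, columns=["snp", "reason"]),
    )


def mv_ivw(instruments: MvInstrumentSet) -> list[MrResult]:
    """Multivariable IVW: per-exposure direct effects with normal inference.

    Weighted least squares of outcome betas on the SNP x exposure effect
    matrix without intercept, weights ``se_y^-2``; residual heterogeneity
    is reported as Q with J - K degrees of freedom.
    """
    X, y, se_y = instruments.bx, instruments.by, instruments.se_y
    j, k_all = X.shape
    if j <= k_all:
        raise ValueError("need more SNPs than exposures")
    # an exposure with no instrument effects at all is inestimable; drop it
    # from the fit so the remaining direct effects are unaffected
    active = ~np.all(X == 0, axis=0)
    Xa = X[:, active]
    k = Xa.shape[1]
    if k == 0:
        raise ValueError("every exposure has all-zero instrument effects")
    if np.linalg.matrix_rank(Xa) < k:
        raise np.linalg.LinAlgError("exposure effect matrix is rank deficient")
    w = se_y**-2
    WX = Xa * w[:, None]
    xtx_inv = np.linalg.inv(Xa.T @ WX)
    coef_a = xtx_inv @ (WX.T @ y)
    ses_a = np.sqrt(np.diag(xtx_inv))
    resid = y - Xa @ coef_a
    q = float((w * resid**2).sum())
    q_p = float(stats.chi2.sf(q, j - k))
    coef = np.full(k_all, np.nan)
    ses = np.full(k_all, np.nan)
    coef[active], ses[active] = coef_a, ses_a
    results = []
    for i, name in enumerate(instruments.exposures):
        beta, se = float(coef[i]), float(ses[i])
        half = 1.959963984540054 * se
        if not active[i]:
            p = np.nan
        elif se > 0:
            p = float(2 * stats.norm.sf(abs(beta / se)))
        else:
            p = 0.0
        results.append(MrResult(
            method="Multivariable IVW", beta=beta, se=se,
            ci_low=beta - half, ci_high=beta + half, p=p, n=j,
            diagnostics={"exposure": name, "estimable": bool(active[i]),
                         "Q": q, "Q_df": j - k, "Q_p": q_p},
        ))
    return results
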