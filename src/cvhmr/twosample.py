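"""Two-sample Mendelian randomization from GWAS summary statistics.

Given per-SNP exposure effects (bx, se_x) and outcome effects (by, se_y)
measured in non-overlapping samples, the per-SNP Wald ratio ``by/bx``
estimates the causal effect; the suite combines ratios with:

* IVW — inverse-variance-weighted regression of by on bx through the
  origin (fixed effect, or multiplicative random effects when Cochran's Q
  indicates heterogeneity);
* weighted median — consistent when valid instruments carry a majority of
  the weight;
* MR-Egger — weighted regression with an intercept; the intercept tests
  directional pleiotropy;
* MR-PRESSO — simulation-based residual-sum-of-squares global test,
  per-SNP outlier flagging and outlier-corrected IVW.

Inputs must first be harmonized so effect alleles agree between the two
tables; palindromic (A/T, C/G) variants are aligned by allele frequency or
dropped when frequencies are uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MrResult, validate_summary_stats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedPairs:
    """Aligned exposure/outcome effects plus the per-SNP harmonization audit.

    ``table`` (the retained SNPs) has columns snp, a1, a2, bx, se_x, by,
    se_y, eaf_x, eaf_y; ``actions`` accounts for every intersected SNP with
    one of kept / flipped / dropped_palindromic / dropped_incompatible.
    """

    table: pd.DataFrame
    actions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def bx(self) -> np.ndarray:
        return self.table["bx"].to_numpy(dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(dtype=float)

    @property
    def by(self) -> np.ndarray:
        return self.table["by"].to_numpy(dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, bx, se_x, by, se_y, snp=None) -> "HarmonizedPairs":
        """Build directly from aligned effect arrays (already harmonized)."""
        bx = np.asarray(bx, dtype=float)
        ids = [f"snp{i + 1}" for i in range(bx.size)] if snp is None else list(snp)
        table = pd.DataFrame({
            "snp": ids, "a1": "A", "a2": "G",
            "bx": bx, "se_x": np.asarray(se_x, dtype=float),
            "by": np.asarray(by, dtype=float), "se_y": np.asarray(se_y, dtype=float),
            "eaf_x": np.nan, "eaf_y": np.nan,
        })
        return cls(table=table)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    eaf_tolerance: float = 0.08,
    palindromic_policy: str = "infer",
) -> HarmonizedPairs:
    """Align outcome effects to the exposure's effect alleles.

    Swapped alleles flip the outcome beta (and complement its EAF); allele
    sets matching only under strand complement are complemented first.
    Palindromic SNPs are aligned via allele frequency when both EAFs are
    outside ``0.5 +/- eaf_tolerance`` (policy ``"infer"``) and dropped
    otherwise, or always dropped under policy ``"drop"``.
    """
    if palindromic_policy not in {"infer", "drop"}:
        raise ValueError("palindromic_policy must be 'infer' or 'drop'")
    exposure = validate_summary_stats(exposure)
    outcome = validate_summary_stats(outcome)
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    if merged.empty:
        raise ValueError("no shared SNPs between exposure and outcome")

    rows, actions = [], []
    for _, r in merged.iterrows():
        a1x, a2x = r["a1_x"], r["a2_x"]
        a1y, a2y = r["a1_y"], r["a2_y"]
        by, eaf_y = r["beta_y"], r["eaf_y"]
        action = None

        if _is_palindromic(a1x, a2x):
            if {a1y, a2y} != {a1x, a2x}:
                action = "dropped_incompatible"
            elif palindromic_policy == "drop":
                action = "dropped_palindromic"
            else:
                informative = (
                    abs(r["eaf_x"] - 0.5) > eaf_tolerance
                    and abs(eaf_y - 0.5) > eaf_tolerance
                )
                if not informative:
                    action = "dropped_palindromic"
                else:
                    # strand-ambiguous: allele labels are uninformative, so
                    # same-side frequencies mean the same allele was measured
                    same_side = (r["eaf_x"] - 0.5) * (eaf_y - 0.5) > 0
                    action = "kept" if same_side else "flipped"
                    if action == "flipped":
                        by, eaf_y = -by, 1 - eaf_y
        else:
            if (a1y, a2y) == (a1x, a2x):
                action = "kept"
            elif (a1y, a2y) == (a2x, a1x):
                action = "flipped"
                by, eaf_y = -by, 1 - eaf_y
            else:
                c1, c2 = _COMPLEMENT.get(a1y), _COMPLEMENT.get(a2y)
                if (c1, c2) == (a1x, a2x):
                    action = "kept"
                elif (c1, c2) == (a2x, a1x):
                    action = "flipped"
                    by, eaf_y = -by, 1 - eaf_y
                else:
                    action = "dropped_incompatible"

        actions.append({"snp": r["snp"], "action": action})
        if action in {"kept", "flipped"}:
            rows.append({
                "snp": r["snp"], "a1": a1x, "a2": a2x,
                "bx": r["beta_x"], "se_x": r["se_x"],
                "by": by, "se_y": r["se_y"],
                "eaf_x": r["eaf_x"], "eaf_y": eaf_y,
            })
    return HarmonizedPairs(
        table=pd.DataFrame(rows, columns=["snp", "a1", "a2", "bx", "se_x",
                                          "by", "se_y", "eaf_x", "eaf_y"]),
        actions=pd.DataFrame(actions),
    )


def wald_ratio(bx: float, se_x: float, by: float, se_y: float) -> tuple[float, float]:
    """Per-SNP causal estimate by/bx with first-order delta-method SE."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    return by / bx, se_y / abs(bx)


def _ivw_point(bx, by, w):
    return float((w * bx * by).sum() / (w * bx * bx).sum())


def ivw(pairs: HarmonizedPairs, mode: str = "auto-random") -> MrResult:
    """Inverse-variance-weighted causal estimate.

    Weighted regression of by on bx through the origin with weights
    ``se_y^-2``.  ``mode="fixed"`` keeps the fixed-effect SE;
    ``"auto-random"`` inflates it by ``sqrt(max(1, Q/(J-1)))``
    (multiplicative random effects) when heterogeneity is present.
    """
    if mode not in {"fixed", "auto-random"}:
        raise ValueError("mode must be 'fixed' or 'auto-random'")
    if len(pairs) < 1:
        raise ValueError("IVW requires at least 1 SNP")
    bx, by, se_y = pairs.bx, pairs.by, pairs.se_y
    w = se_y**-2
    beta = _ivw_point(bx, by, w)
    se = float((w * bx * bx).sum() ** -0.5)
    if len(pairs) >= 2:
        q, df, q_p = cochrans_q(pairs, beta)
        if mode == "auto-random":
            se *= float(np.sqrt(max(1.0, q / df)))
    else:
        # just-identified: the IVW point collapses to the single Wald ratio
        q, df, q_p = 0.0, 0, np.nan
    zstat = beta / se
    half = 1.959963984540054 * se
    return MrResult(
        method="IVW" if mode == "fixed" else "IVW (multiplicative random effects)",
        beta=beta, se=se, ci_low=beta - half, ci_high=beta + half,
        p=float(2 * stats.norm.sf(abs(zstat))), n=len(pairs),
        diagnostics={"Q": q, "Q_df": df, "Q_p": q_p, "mode": mode},
    )


def cochrans_q(pairs: HarmonizedPairs, beta: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test of per-SNP Wald ratios around ``beta``.

    Weights are inverse squared ratio SEs ``(se_y/|bx|)^-2``; returns
    (Q, J-1, upper-tail chi-square p).
    """
    if len(pairs) < 2:
        raise ValueError("Q requires at least 2 SNPs")
    ratios = pairs.by / pairs.bx
    w = (pairs.se_y / np.abs(pairs.bx)) ** -2
    q = float((w * (ratios - beta) ** 2).sum())
    df = len(pairs) - 1
    return q, df, float(stats.chi2.sf(q, df))


def weighted_median_point(ratios, weights) -> float:
    """Weighted median of ``ratios`` by interpolation of cumulative weight.

    Sorts the ratios, forms normalized-weight cumulative midpoints
    ``S_j = sum_{k<=j} w'_k - w'_j/2`` and linearly interpolates the
    ordered ratios at ``S = 0.5``.
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, r))


def weighted_median(pairs: HarmonizedPairs, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Orders per-SNP ratios, accumulates normalized inverse-variance weights
    and interpolates the ordered ratios at cumulative weight 0.5; valid
    when instruments carrying > 50% of the weight satisfy the exclusion
    restriction.
    """
    if len(pairs) < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    bx, by, se_y = pairs.bx, pairs.by, pairs.se_y

    def point(bx_, by_):
        return weighted_median_point(by_ / bx_, (se_y / np.abs(bx_)) ** -2)

    beta = point(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = point(
            rng.normal(bx, pairs.se_x),
            rng.normal(by, se_y),
        )
    se = float(boots.std(ddof=1))
    half = 1.959963984540054 * se
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MrResult(
        method="Weighted median", beta=beta, se=se,
        ci_low=beta - half, ci_high=beta + half, p=p, n=len(pairs),
        diagnostics={"n_boot": n_boot, "seed": seed},
    )


def mr_egger(pairs: HarmonizedPairs) -> tuple[MrResult, dict]:
    """MR-Egger regression: slope = causal estimate, intercept = pleiotropy.

    Pairs are oriented so bx >= 0, then by is regressed on bx with an
    intercept under weights ``se_y^-2``; inference uses t with J-2 df.
    Returns the slope result and an intercept record (estimate, se, p).
    """
    if len(pairs) < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    sign = np.where(pairs.bx < 0, -1.0, 1.0)
    bx, by, se_y = pairs.bx * sign, pairs.by * sign, pairs.se_y
    if np.ptp(bx) == 0:
        raise ValueError("MR-Egger needs spread in |bx| (no leverage)")
    w = se_y**-2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ WX)
    coef = xtx_inv @ (WX.T @ by)
    resid = by - X @ coef
    df = len(pairs) - 2
    # multiplicative overdispersion, floored at 1 (as in the original method)
    phi = max(1.0, float((w * resid**2).sum() / df))
    ses = np.sqrt(np.diag(xtx_inv) * phi)
    tcrit = stats.t.ppf(0.975, df)
    slope, slope_se = float(coef[1]), float(ses[1])
    icpt, icpt_se = float(coef[0]), float(ses[0])
    slope_p = float(2 * stats.t.sf(abs(slope / slope_se), df)) if slope_se > 0 else 0.0
    icpt_p = float(2 * stats.t.sf(abs(icpt / icpt_se), df)) if icpt_se > 0 else 0.0
    result = MrResult(
        method="MR-Egger", beta=slope, se=slope_se,
        ci_low=slope - tcrit * slope_se, ci_high=slope + tcrit * slope_se,
        p=slope_p, n=len(pairs),
        diagnostics={"intercept": icpt, "intercept_se": icpt_se,
                     "intercept_p": icpt_p, "overdispersion": phi},
    )
    return result, {"estimate": icpt, "se": icpt_se, "p": icpt_p}


@dataclass
class PressoResult:
    """MR-PRESSO output: global test, outliers, corrected estimate."""

    global_p: float
    outlier_p: np.ndarray  # Bonferroni-adjusted per-SNP p-values
    outliers: list[int]
    corrected: MrResult | None
    distortion_p: float | None
    rss_observed: float


def _loo_ivw_betas(bx, by, w):
    """Leave-one-out IVW point estimates, O(J) via running sums."""
    num, den = (w * bx * by).sum(), (w * bx * bx).sum()
    return (num - w * bx * by) / (den - w * bx * bx)


def mr_presso(
    pairs: HarmonizedPairs,
    n_sim: int = 1000,
    signif: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO global pleiotropy test with outlier detection/correction.

    The observed residual sum of squares uses leave-one-out IVW predictions;
    its null distribution comes from ``n_sim`` parametric simulations of the
    outcome effects.  Per-SNP outlier p-values are Bonferroni-adjusted over
    J and flagged below ``signif``; the corrected estimate is IVW on the
    unflagged SNPs.  The distortion test compares the observed shift between
    full and corrected estimates with shifts from removing random subsets of
    the same size.
    """
    j = len(pairs)
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 SNPs")
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives unstable empirical p-values")
    bx, by, se_y = pairs.bx, pairs.by, pairs.se_y
    w = se_y**-2

    loo = _loo_ivw_betas(bx, by, w)
    obs_contrib = w * (by - loo * bx) ** 2
    rss_obs = float(obs_contrib.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(loc=loo * bx, scale=se_y, size=(n_sim, j))
    # leave-one-out IVW for every simulated replicate at once
    num_s = by_sim @ (w * bx)
    den = float((w * bx * bx).sum())
    loo_s = (num_s[:, None] - w * bx * by_sim) / (den - w * bx * bx)
    sim_contrib = w * (by_sim - loo_s * bx) ** 2
    rss_sim = sim_contrib.sum(axis=1)
    global_p = float((rss_sim >= rss_obs).mean())

    raw_p = (sim_contrib >= obs_contrib[None, :]).mean(axis=0)
    adj_p = np.minimum(1.0, raw_p * j)
    outliers = [int(i) for i in np.flatnonzero(adj_p < signif)]

    corrected = None
    distortion_p = None
    full_beta = _ivw_point(bx, by, w)
    if outliers and j - len(outliers) >= 2:
        keep = np.ones(j, dtype=bool)
        keep[outliers] = False
        sub = HarmonizedPairs(table=pairs.table.loc[keep].reset_index(drop=True))
        corrected = ivw(sub, mode="fixed")
        if corrected.beta != 0:
            d_obs = (full_beta - corrected.beta) / abs(corrected.beta)
            n_out = len(outliers)
            d_sim = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(j, size=n_out, replace=False)
                keep_s = np.ones(j, dtype=bool)
                keep_s[drop] = False
                b_s = _ivw_point(bx[keep_s], by[keep_s], w[keep_s])
                d_sim[s] = (full_beta - b_s) / abs(b_s) if b_s != 0 else np.inf
            distortion_p = float((np.abs(d_sim) >= abs(d_obs)).mean())
    return PressoResult(
        global_p=global_p, outlier_p=adj_p, outliers=outliers,
        corrected=corrected, distortion_p=distortion_p, rss_observed=rss_obs,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_i = min_{j: p_(j) >= p_(i)} m p_(j) / j`` over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
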