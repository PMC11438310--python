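"""Weighted genetic risk score (wGRS) construction and instrument validation.

A wGRS is ``sum_j w_j g_ij`` over instrument SNPs, with per-allele weights
``w_j`` estimated in an independent base-data GWAS.  Before the score is
used as an instrumental variable, three IV assumptions are audited:

1. relevance — first-stage F statistic (> 10 conventionally "strong");
2. independence — the wGRS must not associate with known confounders
   (two-sample t-test for binary confounders, Pearson correlation test for
   continuous ones);
3. exclusion restriction — the wGRS must not associate with the outcome
   once the exposure and confounders are adjusted for (Wald test of the
   wGRS coefficient).

When a check fails, the pruning loop scores every current SNP against the
violated variable (Cochran-Armitage trend test for binary/categorical,
one-way ANOVA across genotype groups for continuous, adjusted single-SNP
regression for the exclusion check), removes the most-associated SNP,
rebuilds the score and repeats until all checks pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix


@dataclass
class InstrumentSet:
    """wGRS weights, the realized per-individual scores, and the audit log."""

    weights: pd.DataFrame  # columns snp, a1, weight
    wgrs: np.ndarray
    f_stat: float | None = None
    check_log: list = field(default_factory=list)

    @property
    def snps(self) -> list[str]:
        return list(self.weights["snp"])

    @property
    def n_snps(self) -> int:
        return len(self.weights)


def build_wgrs(g: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Per-individual weighted genetic risk score.

    ``weights`` needs columns snp, a1, weight (a2 optional, used for the
    swap check when present).  Each weight's effect allele is reconciled
    with the matrix orientation: matching A1 uses the dosage as is; swapped
    alleles use ``2 - dosage``.  Missing dosages are mean-imputed with
    ``2 * MAF`` (recomputed from the data) before orientation.
    """
    for col in ("snp", "a1", "weight"):
        if col not in weights.columns:
            raise ValueError(f"weights table missing column {col!r}")
    score = np.zeros(g.n_individuals)
    mafs = g.observed_maf()
    meta = g.snps.set_index("snp")
    for _, w in weights.iterrows():
        snp = w["snp"]
        if snp not in meta.index:
            raise KeyError(f"weight SNP {snp!r} absent from genotype matrix")
        j = meta.index.get_loc(snp)
        a1, a2 = meta.loc[snp, "a1"], meta.loc[snp, "a2"]
        dose = g.dosage[:, j].copy()
        dose[np.isnan(dose)] = 2.0 * mafs[j]
        if w["a1"] == a1:
            eff = dose
        elif w["a1"] == a2 and ("a2" not in w or pd.isna(w.get("a2")) or w.get("a2") == a1):
            eff = 2.0 - dose
        else:
            raise ValueError(
                f"alleles for SNP {snp!r} irreconcilable: weight A1={w['a1']!r}, "
                f"matrix A1/A2={a1!r}/{a2!r}"
            )
        score += w["weight"] * eff
    return score


def f_statistic(exposure, wgrs, covariates: pd.DataFrame | None = None) -> float:
    """Partial F statistic for the wGRS term in the first-stage regression.

    Compares exposure ~ covariates + wGRS against the model without the
    wGRS; with no covariates this reduces to ``(n-2) R^2 / (1 - R^2)``.
    """
    y = np.asarray(exposure, dtype=float)
    z = np.asarray(wgrs, dtype=float)
    if y.shape != z.shape:
        raise ValueError("exposure and wGRS must align")
    n = y.size
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    X_red = np.column_stack([np.ones(n), C])
    X_full = np.column_stack([X_red, z])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise np.linalg.LinAlgError("collinear design in first-stage F computation")
    p_full = X_full.shape[1]
    if n <= p_full + 1:
        raise ValueError("too few observations for the first-stage model")

    def rss(X):
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r

    rss_red, rss_full = rss(X_red), rss(X_full)
    return float((rss_red - rss_full) / (rss_full / (n - p_full)))


def _is_binary(x: np.ndarray) -> bool:
    return np.unique(x[~np.isnan(x)]).size == 2


def _wald_p_last(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
    if se == 0:
        return 0.0
    return float(2 * stats.t.sf(abs(beta[-1] / se), df))


def assumption_report(
    wgrs,
    confounders: pd.DataFrame,
    eaa,
    exposure,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Audit the independence and exclusion-restriction assumptions.

    One row per confounder (independence) plus one exclusion row for the
    outcome; columns: check, variable, test, p, passed.  Binary confounders
    use a two-sample t-test of the wGRS between groups, continuous ones a
    Pearson correlation test; the exclusion row is the Wald p of the wGRS
    in outcome ~ wGRS + exposure + confounders.  A row passes iff
    ``p >= alpha``.
    """
    z = np.asarray(wgrs, dtype=float)
    y = np.asarray(eaa, dtype=float)
    x = np.asarray(exposure, dtype=float)
    rows = []
    for name in confounders.columns:
        c = np.asarray(confounders[name], dtype=float)
        if _is_binary(c):
            levels = np.unique(c[~np.isnan(c)])
            g0, g1 = z[c == levels[0]], z[c == levels[1]]
            if g0.size < 2 or g1.size < 2:
                rows.append({"check": "independence", "variable": name,
                             "test": "two-sample t", "p": np.nan, "passed": None})
                continue
            p = stats.ttest_ind(g0, g1).pvalue
            test = "two-sample t"
        else:
            p = stats.pearsonr(z, c).pvalue
            test = "pearson"
        rows.append({"check": "independence", "variable": name, "test": test,
                     "p": float(p), "passed": bool(p >= alpha)})
    C = np.asarray(confounders, dtype=float)
    X = np.column_stack([np.ones(z.size), x, C, z])
    p_excl = _wald_p_last(X, y)
    rows.append({"check": "exclusion", "variable": "outcome", "test": "wald",
                 "p": p_excl, "passed": bool(p_excl >= alpha)})
    return pd.DataFrame(rows)


def cochran_armitage_trend(counts) -> tuple[float, float]:
    """Cochran-Armitage trend test for a 2 x 3 trait-by-genotype table.

    Rows are the two trait groups, columns the genotype dosage groups
    scored (0, 1, 2).  Returns (Z, two-sided normal p).
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 table of counts")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    n = t.sum()
    row1 = t[1].sum()
    col = t.sum(axis=0)
    if n == 0 or row1 == 0 or row1 == n:
        raise ValueError("both trait groups must be non-empty")
    scores = np.array([0.0, 1.0, 2.0])
    if np.count_nonzero(col) <= 1:
        raise ValueError("trend untestable: all mass in one genotype column")
    stat = scores @ (t[1] - row1 * col / n)
    pbar = row1 / n
    var = pbar * (1 - pbar) * (scores**2 @ col - (scores @ col) ** 2 / n)
    z = stat / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _per_snp_violation_p(
    g: GenotypeMatrix,
    snp: str,
    variable: np.ndarray,
    check: str,
    exposure: np.ndarray,
    confounders: pd.DataFrame,
    eaa: np.ndarray,
) -> float:
    """p-value of one SNP against the violated variable."""
    dose = g.column(snp)
    ok = ~np.isnan(dose)
    if check == "exclusion":
        C = np.asarray(confounders, dtype=float)[ok]
        X = np.column_stack([np.ones(ok.sum()), exposure[ok], C, dose[ok]])
        return _wald_p_last(X, eaa[ok])
    v = variable[ok]
    geno = np.rint(dose[ok]).astype(int)
    if _is_binary(variable):
        levels = np.unique(v)
        table = np.array([[np.sum((v == lev) & (geno == k)) for k in (0, 1, 2)] for lev in levels])
        try:
            _, p = cochran_armitage_trend(table)
        except ValueError:
            p = 1.0
        return p
    groups = [v[geno == k] for k in (0, 1, 2) if np.sum(geno == k) >= 2]
    if len(groups) < 2:
        return 1.0
    return float(stats.f_oneway(*groups).pvalue)


def prune_instrument(
    g: GenotypeMatrix,
    instrument: InstrumentSet,
    confounders: pd.DataFrame,
    eaa,
    exposure,
    alpha: float = 0.05,
    min_snps: int = 2,
) -> InstrumentSet:
    """Iteratively remove SNPs until the wGRS passes all assumption checks.

    At each round the most significant failing check is addressed: every
    current SNP is tested against the violated variable and the SNP with
    the smallest p-value is dropped; the wGRS is rebuilt and the checks are
    repeated.  Raises if the SNP count would fall below ``min_snps`` with a
    check still failing.  Every removal is appended to the check log.
    """
    eaa = np.asarray(eaa, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    weights = instrument.weights.copy()
    log = list(instrument.check_log)
    if len(weights) < min_snps:
        raise ValueError("instrument smaller than min_snps at entry")
    while True:
        wgrs = build_wgrs(g, weights)
        report = assumption_report(wgrs, confounders, eaa, exposure, alpha=alpha)
        failing = report[report["passed"] == False]  # noqa: E712 — None rows excluded
        if failing.empty:
            return InstrumentSet(weights=weights.reset_index(drop=True), wgrs=wgrs,
                                 check_log=log)
        worst = failing.sort_values("p").iloc[0]
        if len(weights) <= min_snps:
            raise RuntimeError(
                f"cannot prune below {min_snps} SNPs; unresolved check: "
                f"{worst['check']} on {worst['variable']} (p={worst['p']:.3g})"
            )
        variable = (
            eaa if worst["check"] == "exclusion"
            else np.asarray(confounders[worst["variable"]], dtype=float)
        )
        snp_ps = {
            snp: _per_snp_violation_p(g, snp, variable, worst["check"],
                                      exposure, confounders, eaa)
            for snp in weights["snp"]
        }
        removed = min(sorted(snp_ps), key=lambda s: (snp_ps[s], s))
        log.append({
            "action": "remove", "snp": removed, "check": worst["check"],
            "variable": worst["variable"], "check_p": float(worst["p"]),
            "snp_p": float(snp_ps[removed]),
        })
        weights = weights[weights["snp"] != removed]


def replay_check_log(instrument: InstrumentSet, initial_weights: pd.DataFrame) -> list[str]:
    """Reapply the logged removals to the initial weights; returns SNP ids."""
    kept = list(initial_weights["snp"])
    for entry in instrument.check_log:
        if entry.get("action") == "remove":
            kept.remove(entry["snp"])
    return kept
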