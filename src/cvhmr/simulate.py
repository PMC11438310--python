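"""Synthetic cohorts and summary statistics with known causal ground truth.

The individual-level generator draws Hardy-Weinberg genotypes, builds raw
cardiovascular-health metrics from per-SNP and confounder effects, scores
them, and produces epigenetic-age-acceleration (EAA) outcomes as

    EAA = theta * CVH_total + confounder effects + sum_j pleiotropy_j g_j + noise

so ``theta`` (the causal effect per CVH point) and every violating path are
known exactly.  The two-sample generator draws per-SNP effect estimates
around their true values, optionally with directional or balanced
pleiotropy and planted outliers, emulating non-overlapping exposure and
outcome GWAS.

Defaults mimic a middle-aged population cohort: age ~ Normal(50, 11)
truncated to [30, 70], sex and drinking Bernoulli, education an integer
1-7.  SNPs are independent by default; an optional block-correlated mode
exists solely to exercise LD clumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .cvh import score_table

_COMPONENT_ORDER = ("tc", "fg", "sbp", "dbp", "bmi")

#: Baseline raw-metric means/SDs for the continuous components (mg/dL, mmHg,
#: kg/m^2) — centred near the intermediate/ideal boundaries so genetic and
#: confounder effects move individuals across score categories.
_BASELINES = {
    "tc": (200.0, 35.0),
    "fg": (100.0, 15.0),
    "sbp": (120.0, 15.0),
    "dbp": (78.0, 10.0),
    "bmi": (24.0, 3.5),
}


@dataclass
class CohortSimConfig:
    """Generating parameters for an individual-level cohort.

    ``snp_effects`` maps a continuous component (tc, fg, sbp, dbp, bmi) to a
    per-SNP effect vector in component units per A1 allele; unlisted
    components get zero effects.  ``theta`` maps outcome name -> causal
    effect of the total CVH score (outcome units per point).  ``pleiotropy``
    maps outcome name -> per-SNP direct effects (outcome units per allele).
    """

    n_individuals: int = 2000
    n_snps: int = 15
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_effects: dict = field(default_factory=dict)
    confounder_effects_exposure: dict = field(default_factory=dict)
    confounder_effects_outcome: dict = field(default_factory=dict)
    theta: dict = field(default_factory=lambda: {"GrimEAA": -1.0})
    pleiotropy: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    ld_blocks: int = 0  # >0 adds ld_blocks duplicated-with-noise SNP pairs
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_snps < 1 or self.n_individuals < 1:
            raise ValueError("n_snps and n_individuals must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for comp, eff in self.snp_effects.items():
            if comp not in _COMPONENT_ORDER:
                raise ValueError(f"unknown component {comp!r}")
            if len(eff) != self.n_snps:
                raise ValueError(
                    f"effect vector for {comp!r} has length {len(eff)}, "
                    f"expected n_snps={self.n_snps}"
                )
        for out, eff in self.pleiotropy.items():
            if np.ndim(eff) and len(eff) != self.n_snps:
                raise ValueError(f"pleiotropy vector for {out!r} must have n_snps entries")


def simulate_genotypes(
    n_individuals: int,
    mafs,
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom=None,
    pos=None,
) -> GenotypeMatrix:
    """Draw unlinked genotypes in Hardy-Weinberg proportions.

    Each SNP column is Binomial(2, maf) counts of the minor (A1) allele;
    missing entries are set completely at random to NaN.
    """
    mafs = np.asarray(mafs, dtype=float)
    if n_individuals < 1:
        raise ValueError("n_individuals must be positive")
    bad = np.flatnonzero((mafs <= 0) | (mafs > 0.5))
    if bad.size:
        raise ValueError(f"MAF outside (0, 0.5] for SNP index {bad[0]} (maf={mafs[bad[0]]})")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, mafs, size=(n_individuals, mafs.size)).astype(float)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan
    m = mafs.size
    alleles = np.array([["A", "G"], ["C", "T"], ["A", "C"], ["G", "T"]])
    pick = np.arange(m) % len(alleles)
    snps = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chrom": np.ones(m, dtype=int) if chrom is None else chrom,
        "pos": (np.arange(m) + 1) * 100_000 if pos is None else pos,
        "a1": alleles[pick, 0],
        "a2": alleles[pick, 1],
        "maf": mafs,
    })
    return GenotypeMatrix(dosage=dosage, snps=snps)


def _simulate_confounders(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(50.0, 11.0, n), 30.0, 70.0)
    return pd.DataFrame({
        "age": age,
        "sex": rng.binomial(1, 0.5, n).astype(float),
        "drinking": rng.binomial(1, 0.07, n).astype(float),
        "education": rng.integers(1, 8, n).astype(float),
    })


def simulate_cohort(config: CohortSimConfig):
    """Generate (genotypes, covariates, raw CVH metrics, EAA outcomes, truth).

    Raw continuous components are baseline + SNP effects + confounder
    effects + Gaussian noise; smoking and physical activity are drawn
    categorically; outcomes follow the structural model described in the
    module docstring.  The truth record stores every generating parameter.
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    geno = simulate_genotypes(
        config.n_individuals, mafs, config.missing_rate,
        seed=int(rng.integers(2**31)),
    )
    n = config.n_individuals
    cov = _simulate_confounders(n, rng)
    # analysis uses complete dosages internally; missing entries only affect
    # what downstream QC/wGRS see
    complete = np.where(np.isnan(geno.dosage), 0.0, geno.dosage)
    cexp = config.confounder_effects_exposure

    metrics = pd.DataFrame(index=range(n))
    for comp in _COMPONENT_ORDER:
        base, sd = _BASELINES[comp]
        value = np.full(n, base)
        eff = config.snp_effects.get(comp)
        if eff is not None:
            value = value + complete @ np.asarray(eff, dtype=float)
        for cname, ceff in cexp.get(comp, {}).items():
            value = value + ceff * cov[cname].to_numpy()
        noise = config.noise_sd.get(comp, sd)
        metrics[comp] = value + rng.normal(0.0, noise, n)
    metrics["tc"] = np.maximum(metrics["tc"], 80.0)
    metrics["fg"] = np.maximum(metrics["fg"], 50.0)
    metrics["sbp"] = np.maximum(metrics["sbp"], 70.0)
    metrics["dbp"] = np.maximum(metrics["dbp"], 40.0)
    metrics["bmi"] = np.maximum(metrics["bmi"], 14.0)
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.7, 0.1, 0.2])
    quit_months = np.where(smoking == "former", rng.integers(0, 120, n).astype(float), np.nan)
    metrics["smoking"] = smoking
    metrics["quit_months"] = quit_months
    metrics["pa"] = rng.choice(["never", "between", "regular"], size=n, p=[0.45, 0.25, 0.30])

    scores = score_table(metrics)
    cvh_total = scores["cvh_score"].to_numpy(dtype=float)

    cout = config.confounder_effects_outcome
    outcomes = pd.DataFrame(index=range(n))
    for out, theta in config.theta.items():
        value = theta * cvh_total
        for cname, ceff in cout.get(out, {}).items():
            value = value + ceff * cov[cname].to_numpy()
        pleio = config.pleiotropy.get(out)
        if pleio is not None:
            value = value + complete @ np.asarray(pleio, dtype=float)
        value = value + rng.normal(0.0, config.noise_sd.get(out, 1.0), n)
        outcomes[out] = value

    truth = {
        "theta": dict(config.theta),
        "mafs": mafs.tolist(),
        "snp_effects": {k: list(map(float, v)) for k, v in config.snp_effects.items()},
        "pleiotropy": {k: list(map(float, np.atleast_1d(v)))
                       for k, v in config.pleiotropy.items()},
        "confounder_effects_exposure": cexp,
        "confounder_effects_outcome": cout,
        "seed": config.seed,
    }
    return geno, cov, metrics, pd.concat([scores, outcomes], axis=1), truth


@dataclass
class TwoSampleSimConfig:
    """Generating parameters for exposure/outcome summary statistics."""

    n_snps: int = 30
    beta_x: np.ndarray | None = None
    # default exposure SE keeps every instrument genome-wide significant
    # (|beta_x|/se_x >= 5 for the smallest effects), as p < 5E-8 selection implies
    se_x: np.ndarray | float = 0.01
    se_y: np.ndarray | float = 0.05
    theta: float = -0.5
    alpha: np.ndarray | float = 0.0  # per-SNP direct (pleiotropic) effects
    outlier_indices: frozenset = frozenset()
    outlier_scale: float = 20.0  # outlier alpha in units of that SNP's se_y
    palindromic_fraction: float = 0.0
    seed: int = 0

    def _vectors(self):
        rng = np.random.default_rng(self.seed)
        bx = (np.asarray(self.beta_x, dtype=float) if self.beta_x is not None
              else rng.uniform(0.05, 0.2, self.n_snps) * rng.choice([-1, 1], self.n_snps))
        se_x = np.broadcast_to(np.asarray(self.se_x, dtype=float), bx.shape).copy()
        se_y = np.broadcast_to(np.asarray(self.se_y, dtype=float), bx.shape).copy()
        alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), bx.shape).copy()
        if bx.size != self.n_snps:
            raise ValueError("beta_x length must equal n_snps")
        if (se_x <= 0).any() or (se_y <= 0).any():
            raise ValueError("all standard errors must be positive")
        for i in self.outlier_indices:
            alpha[i] = self.outlier_scale * se_y[i]
        return bx, se_x, se_y, alpha, rng


def simulate_summary_stats(config: TwoSampleSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw exposure and outcome summary-statistic tables.

    Exposure estimates are Normal(beta_x_j, se_x_j); outcome estimates are
    Normal(theta*beta_x_j + alpha_j, se_y_j).  A configurable fraction of
    SNPs receives palindromic (A/T, C/G) allele pairs; effect-allele
    frequencies are populated and shared (with small noise) between tables.
    """
    bx, se_x, se_y, alpha, rng = config._vectors()
    m = config.n_snps
    bx_hat = rng.normal(bx, se_x)
    by_hat = rng.normal(config.theta * bx + alpha, se_y)
    eaf = rng.uniform(0.05, 0.45, m)
    n_pal = int(round(config.palindromic_fraction * m))
    is_pal = np.zeros(m, dtype=bool)
    is_pal[:n_pal] = True
    pal_pairs = np.array([["A", "T"], ["C", "G"]])
    reg_pairs = np.array([["A", "G"], ["C", "T"], ["A", "C"], ["G", "T"]])
    a1 = np.where(is_pal, pal_pairs[np.arange(m) % 2, 0], reg_pairs[np.arange(m) % 4, 0])
    a2 = np.where(is_pal, pal_pairs[np.arange(m) % 2, 1], reg_pairs[np.arange(m) % 4, 1])
    ids = [f"rs{i + 1}" for i in range(m)]

    def table(beta, se):
        p = 2 * _norm_sf(np.abs(beta / se))
        return pd.DataFrame({
            "snp": ids, "a1": a1, "a2": a2, "eaf": eaf,
            "beta": beta, "se": se, "p": np.clip(p, 1e-300, 1.0),
            "n": 50_000,
        })

    exposure = table(bx_hat, se_x)
    outcome = table(by_hat, se_y)
    outcome["eaf"] = np.clip(eaf + rng.normal(0, 0.005, m), 0.01, 0.99)
    return exposure, outcome


def _norm_sf(z):
    from scipy import stats

    return stats.norm.sf(z)
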