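"""Umbrella pipeline: score -> GWAS -> clump -> wGRS -> checks -> 2SLS,
or harmonize -> estimator suite -> FDR in two-sample mode.

Configuration is a plain mapping (usually loaded from YAML); all
randomness flows from a single ``seed`` fanned out deterministically per
stage, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .containers import GenotypeMatrix
from .gwas import ClumpSpec, assoc_scan, clump, qc_filter
from .instruments import InstrumentSet, build_wgrs, f_statistic, prune_instrument
from .onesample import tsls
from .twosample import bh_fdr, harmonize, ivw, mr_egger, mr_presso, weighted_median

log = logging.getLogger("cvhmr")


@dataclass
class PipelineConfig:
    """Validated thresholds, seeds and toggles for a pipeline run."""

    mode: str = "one-sample"
    seed: int = 0
    n_base: int = 20_000
    n_target: int = 2_000
    n_snps: int = 15
    theta: dict = field(default_factory=lambda: {"GrimEAA": -1.0})
    snp_effect_sd: float = 2.0
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0
    hwe_p_min: float = 5.7e-7
    call_rate_min: float = 0.95
    maf_min: float = 0.01
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def _derived_seed(seed: int, stage: str) -> int:
    # stable per-stage fan-out (zlib.crc32 is deterministic across processes,
    # unlike str.__hash__)
    import zlib

    mix = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(mix.generate_state(1, dtype=np.uint32)[0] % 2**31)


def run_one_sample(config: PipelineConfig) -> dict:
    """Simulated end-to-end one-sample MR run with a base/target split.

    Per-SNP effects on the continuous CVH components are drawn once from
    Normal(0, snp_effect_sd); the base cohort (no outcome data needed)
    estimates SNP weights via GWAS + clumping, the target cohort carries
    the wGRS into assumption checks and 2SLS.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    effects = {
        comp: rng.normal(0.0, config.snp_effect_sd, m)
        for comp in ("tc", "fg", "sbp", "dbp", "bmi")
    }
    conf_exp = {"bmi": {"age": 0.02, "sex": 0.5}}
    conf_out = {out: {"age": 0.05, "sex": 0.3, "drinking": 0.2, "education": -0.1}
                for out in config.theta}

    base_cfg = sim.CohortSimConfig(
        n_individuals=config.n_base, n_snps=m, snp_effects=effects,
        confounder_effects_exposure=conf_exp, confounder_effects_outcome=conf_out,
        theta=config.theta, seed=_derived_seed(config.seed, "base"),
    )
    target_cfg = sim.CohortSimConfig(
        n_individuals=config.n_target, n_snps=m, snp_effects=effects,
        confounder_effects_exposure=conf_exp, confounder_effects_outcome=conf_out,
        theta=config.theta, seed=_derived_seed(config.seed, "target"),
    )
    g_base, cov_base, _, tab_base, _ = sim.simulate_cohort(base_cfg)
    g_target, cov_target, _, tab_target, truth = sim.simulate_cohort(target_cfg)
    log.info("simulated base n=%d, target n=%d, %d SNPs", config.n_base,
             config.n_target, m)

    g_base, qc_log = qc_filter(g_base, config.call_rate_min, config.hwe_p_min,
                               config.maf_min)
    log.info("QC kept %d SNPs (dropped %d)", g_base.n_snps, len(qc_log))

    assoc = assoc_scan(g_base, tab_base["cvh_score"], cov_base)
    spec = ClumpSpec(config.p_threshold, config.r2_threshold, config.window_kb)
    index_snps = clump(assoc, g_base, spec)
    log.info("clumping kept %d index SNPs at p<%g, r2<%g within %g kb",
             len(index_snps), spec.p_threshold, spec.r2_threshold, spec.window_kb)
    if not index_snps:
        raise RuntimeError("no genome-wide significant SNPs; cannot build wGRS")

    weights = (
        assoc.set_index("snp").loc[index_snps]
        .reset_index()[["snp", "a1", "beta"]]
        .rename(columns={"beta": "weight"})
    )
    g_iv = g_target.subset(index_snps)
    instrument = InstrumentSet(weights=weights, wgrs=build_wgrs(g_iv, weights))

    results = []
    audit_logs = {}
    for outcome in config.theta:
        eaa = tab_target[outcome].to_numpy(dtype=float)
        exposure = tab_target["cvh_score"].to_numpy(dtype=float)
        pruned = prune_instrument(g_iv, instrument, cov_target, eaa, exposure,
                                  alpha=config.alpha)
        f_val = f_statistic(exposure, pruned.wgrs, cov_target)
        res = tsls(exposure, eaa, pruned.wgrs, cov_target)
        results.append({
            "outcome": outcome, "iv": f"CVH-wGRS ({pruned.n_snps} SNPs)",
            "F": f_val, "beta": res.beta, "se": res.se,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
            "n": res.n, "theta_true": config.theta[outcome],
        })
        audit_logs[outcome] = pruned.check_log
    report = pd.DataFrame(results)
    bundle = {
        "report": report, "qc_log": qc_log, "assoc": assoc,
        "index_snps": index_snps, "weights": weights,
        "audit_logs": audit_logs, "truth": truth,
    }
    _write_bundle(bundle, config)
    return bundle


def run_two_sample(config: PipelineConfig, exposure=None, outcome=None) -> dict:
    """Two-sample estimator suite on given or simulated summary statistics."""
    if exposure is None or outcome is None:
        ts_cfg = sim.TwoSampleSimConfig(
            n_snps=max(config.n_snps, 10),
            theta=next(iter(config.theta.values())),
            seed=_derived_seed(config.seed, "two-sample"),
        )
        exposure, outcome = sim.simulate_summary_stats(ts_cfg)
    pairs = harmonize(exposure, outcome)
    log.info("harmonized %d SNPs (%s)", len(pairs),
             pairs.actions["action"].value_counts().to_dict())
    res_ivw = ivw(pairs)
    res_wm = weighted_median(pairs, n_boot=config.n_boot,
                             seed=_derived_seed(config.seed, "wm-boot"))
    res_egger, intercept = mr_egger(pairs)
    presso = mr_presso(pairs, n_sim=config.n_sim,
                       seed=_derived_seed(config.seed, "presso"))
    rows = [r.to_dict() for r in (res_ivw, res_wm, res_egger)]
    if presso.corrected is not None:
        corr = presso.corrected.to_dict()
        corr["method"] = "MR-PRESSO (outlier-corrected)"
        rows.append(corr)
    report = pd.DataFrame(rows)
    report["q"] = bh_fdr(report["p"].clip(lower=1e-300))
    bundle = {
        "report": report, "harmonization": pairs.actions,
        "egger_intercept": intercept,
        "presso": {"global_p": presso.global_p, "outliers": presso.outliers,
                   "distortion_p": presso.distortion_p},
        "Q": res_ivw.diagnostics["Q"], "Q_p": res_ivw.diagnostics["Q_p"],
    }
    _write_bundle(bundle, config)
    return bundle


def run_pipeline(config: PipelineConfig | dict) -> dict:
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    if config.mode == "one-sample":
        return run_one_sample(config)
    if config.mode == "two-sample":
        return run_two_sample(config)
    raise ValueError(f"unknown pipeline mode {config.mode!r}")


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    import json

    scalars = {k: v for k, v in bundle.items()
               if not isinstance(v, (pd.DataFrame, list, GenotypeMatrix))}
    with open(out / "summary.json", "w") as fh:
        json.dump(scalars, fh, indent=2, default=str)
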