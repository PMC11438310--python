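"""Readers and writers for the tab-separated and VCF formats used throughout.

Summary-statistics tables follow the GWAS-catalog-style column layout
SNP, A1, A2, EAF, BETA, SE, P, N; genotype dosage matrices are SNP-major
TSV with metadata columns followed by one column per sample.  Invalid
summary rows are routed to a sidecar rejects table with a reason, never
silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SUMMARY_COLUMNS, GenotypeMatrix

_DEFAULT_COLUMN_MAP = {
    "SNP": "snp", "A1": "a1", "A2": "a2", "EAF": "eaf",
    "BETA": "beta", "SE": "se", "P": "p", "N": "n",
}
_BASES = frozenset("ACGT")


def read_summary_stats(
    path,
    column_map: dict | None = None,
    allow_indels: bool = False,
    rejects_path=None,
):
    """Read and validate a summary-statistics TSV.

    ``column_map`` maps file headers to canonical names (defaults cover
    SNP/A1/A2/EAF/BETA/SE/P/N).  Rows with non-positive SE, or non-ACGT
    alleles under strict mode, go to a rejects table (written to
    ``rejects_path`` when given) with a reason column.  Returns
    ``(stats, rejects)``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    cmap = {**_DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    df = df[SUMMARY_COLUMNS].copy()
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()

    reasons = pd.Series("", index=df.index)
    bad_se = df["se"] <= 0
    reasons[bad_se] = "nonpositive_se"
    if not allow_indels:
        bad_allele = ~(df["a1"].isin(_BASES) & df["a2"].isin(_BASES))
        reasons[bad_allele & (reasons == "")] = "non_single_base_allele"
    bad = reasons != ""
    rejects = df[bad].assign(reason=reasons[bad])
    kept = df[~bad].reset_index(drop=True)
    if rejects_path is not None:
        rejects.to_csv(rejects_path, sep="\t", index=False)
    return kept, rejects.reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path) -> None:
    out = df[SUMMARY_COLUMNS].rename(
        columns={v: k for k, v in _DEFAULT_COLUMN_MAP.items()}
    )
    out.to_csv(path, sep="\t", index=False)


def write_genotypes(g: GenotypeMatrix, path, sample_ids=None) -> None:
    """Write a SNP-major dosage TSV (metadata columns, then one per sample)."""
    n = g.n_individuals
    ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    table = g.snps.copy()
    dose = pd.DataFrame(g.dosage.T, columns=ids)
    pd.concat([table.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_genotypes(path, fmt: str = "dosage-tsv") -> GenotypeMatrix:
    """Read genotypes from a dosage TSV or an (uncompressed or bgzipped) VCF.

    VCF GT fields are converted to counts of the ALT allele (A1 = ALT);
    missing calls become missing dosages; multi-allelic records are
    rejected with their position.
    """
    if fmt == "dosage-tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        meta_cols = ["snp", "chrom", "pos", "a1", "a2", "maf"]
        snps = df[meta_cols].copy()
        dose = df.drop(columns=meta_cols).to_numpy(dtype=float).T
        return GenotypeMatrix(dosage=dose, snps=snps)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover
        return _read_vcf_text(path)
    rows, doses = [], []
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported"
            )
        gts = np.asarray(rec.genotypes, dtype=object)
        d = np.empty(len(gts))
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            d[i] = np.nan if (a < 0 or b < 0) else float((a > 0) + (b > 0))
        doses.append(d)
        maf = np.nanmean(d) / 2 if np.isfinite(np.nanmean(d)) else np.nan
        rows.append({
            "snp": rec.ID or f"{rec.CHROM}:{rec.POS}",
            "chrom": rec.CHROM, "pos": rec.POS,
            "a1": rec.ALT[0], "a2": rec.REF, "maf": maf,
        })
    return GenotypeMatrix(dosage=np.array(doses).T, snps=pd.DataFrame(rows))


def _read_vcf_text(path) -> GenotypeMatrix:
    """Minimal fallback parser for plain-text VCF with GT-only FORMAT."""
    rows, doses = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            if "," in alt:
                raise ValueError(f"multi-allelic record at {chrom}:{pos} not supported")
            gt_idx = f[8].split(":").index("GT")
            d = []
            for sample in f[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    d.append(np.nan)
                else:
                    d.append(float(sum(int(a) > 0 for a in gt.split("/"))))
            d = np.array(d)
            doses.append(d)
            rows.append({
                "snp": vid if vid != "." else f"{chrom}:{pos}",
                "chrom": chrom, "pos": pos, "a1": alt, "a2": ref,
                "maf": np.nanmean(d) / 2,
            })
    return GenotypeMatrix(dosage=np.array(doses).T, snps=pd.DataFrame(rows))


def read_config(path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
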