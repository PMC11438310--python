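"""Twelve-point cardiovascular-health (CVH) scoring.

Six metrics — total cholesterol (TC), fasting glucose (FG), blood pressure
(BP), body-mass index (BMI), smoking status (SMK) and physical activity
(PA) — are each scored 0 (poor), 1 (intermediate) or 2 (ideal) and summed to
a composite score between 0 and 12.  The diet metric of the original
American Heart Association definition is deliberately excluded (the
"12-point" variant).  All lower bounds are inclusive and upper bounds
exclusive, e.g. the intermediate BMI band is ``24 <= BMI < 27``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SMOKING_LEVELS = ("current", "former", "never")
PA_LEVELS = ("never", "between", "regular")
COMPONENTS = ("tc", "fg", "bp", "bmi", "smk", "pa")


@dataclass(frozen=True)
class CvhRecord:
    """Raw clinical and lifestyle metrics for one participant.

    Units: tc and fg in mg/dL, sbp/dbp in mmHg, bmi in kg/m^2.
    ``quit_months`` is required iff ``smoking == "former"``.
    """

    tc: float
    fg: float
    sbp: float
    dbp: float
    bmi: float
    smoking: str
    pa: str
    quit_months: float | None = None

    def __post_init__(self) -> None:
        for name in ("tc", "fg", "sbp", "dbp", "bmi"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive number, got {value!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"smoking must be one of {SMOKING_LEVELS}, got {self.smoking!r}")
        if self.pa not in PA_LEVELS:
            raise ValueError(f"pa must be one of {PA_LEVELS}, got {self.pa!r}")
        if self.smoking == "former":
            if self.quit_months is None:
                raise ValueError("former smoker requires quit_months")
            if self.quit_months < 0:
                raise ValueError("quit_months must be >= 0")


@dataclass(frozen=True)
class CvhScores:
    """Component scores (each 0/1/2) and their 0-12 total."""

    tc: int
    fg: int
    bp: int
    bmi: int
    smk: int
    pa: int

    @property
    def total(self) -> int:
        return self.tc + self.fg + self.bp + self.bmi + self.smk + self.pa

    def as_dict(self) -> dict:
        return {
            "tc_score": self.tc,
            "fg_score": self.fg,
            "bp_score": self.bp,
            "bmi_score": self.bmi,
            "smk_score": self.smk,
            "pa_score": self.pa,
            "cvh_score": self.total,
        }


def _band(value: float, low: float, high: float) -> int:
    """2 below ``low``, 1 in [low, high), 0 at or above ``high``."""
    if value < low:
        return 2
    if value < high:
        return 1
    return 0


def score_component(metric: str, record: CvhRecord) -> int:
    """Score one CVH metric of ``record`` as 0 (poor), 1 or 2 (ideal).

    BP is classified poor-first (SBP >= 140 or DBP >= 90), ideal-second
    (SBP < 120 and DBP < 80), else intermediate — equivalent to the
    two-clause intermediate definition but with no gaps at compound
    boundaries.
    """
    metric = metric.lower()
    if metric == "tc":
        return _band(record.tc, 200.0, 240.0)
    if metric == "fg":
        return _band(record.fg, 100.0, 126.0)
    if metric == "bmi":
        return _band(record.bmi, 24.0, 27.0)
    if metric == "bp":
        if record.sbp >= 140.0 or record.dbp >= 90.0:
            return 0
        if record.sbp < 120.0 and record.dbp < 80.0:
            return 2
        return 1
    if metric == "smk":
        if record.smoking == "current":
            return 0
        if record.smoking == "never":
            return 2
        return 2 if record.quit_months >= 6.0 else 1
    if metric == "pa":
        return {"never": 0, "between": 1, "regular": 2}[record.pa]
    raise ValueError(f"unknown CVH metric {metric!r}")


def cvh_total(record: CvhRecord) -> CvhScores:
    """Score all six metrics and return the component scores with their total."""
    return CvhScores(*(score_component(m, record) for m in COMPONENTS))


def score_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Score a table of raw metrics (one row per participant), vectorized.

    Expects columns tc, fg, sbp, dbp, bmi, smoking, pa and optionally
    quit_months; returns the six component scores plus ``cvh_score``.
    Applies the same category rules as :func:`score_component`.
    """
    for col in ("tc", "fg", "sbp", "dbp", "bmi", "smoking", "pa"):
        if col not in metrics.columns:
            raise ValueError(f"metrics table missing column {col!r}")

    def band(values, low, high):
        v = np.asarray(values, dtype=float)
        return np.where(v < low, 2, np.where(v < high, 1, 0))

    out = pd.DataFrame(index=metrics.index)
    out["tc_score"] = band(metrics["tc"], 200.0, 240.0)
    out["fg_score"] = band(metrics["fg"], 100.0, 126.0)
    sbp = np.asarray(metrics["sbp"], dtype=float)
    dbp = np.asarray(metrics["dbp"], dtype=float)
    out["bp_score"] = np.where(
        (sbp >= 140.0) | (dbp >= 90.0), 0,
        np.where((sbp < 120.0) & (dbp < 80.0), 2, 1),
    )
    out["bmi_score"] = band(metrics["bmi"], 24.0, 27.0)
    smoking = metrics["smoking"].astype(str)
    bad_smk = ~smoking.isin(SMOKING_LEVELS)
    if bad_smk.any():
        raise ValueError(f"invalid smoking level {smoking[bad_smk].iloc[0]!r}")
    quit_months = (
        np.asarray(metrics["quit_months"], dtype=float)
        if "quit_months" in metrics.columns
        else np.full(len(metrics), np.nan)
    )
    former = (smoking == "former").to_numpy()
    if np.isnan(quit_months[former]).any():
        raise ValueError("former smoker requires quit_months")
    out["smk_score"] = np.where(
        smoking == "current", 0,
        np.where(smoking == "never", 2, np.where(quit_months >= 6.0, 2, 1)),
    )
    pa = metrics["pa"].astype(str)
    bad_pa = ~pa.isin(PA_LEVELS)
    if bad_pa.any():
        raise ValueError(f"invalid physical-activity level {pa[bad_pa].iloc[0]!r}")
    out["pa_score"] = pa.map({"never": 0, "between": 1, "regular": 2}).to_numpy()
    out["cvh_score"] = out.sum(axis=1)
    return out


def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and sample (n-1 denominator) SD 1.

    Used for outcomes reported on an arbitrary scale (e.g. DNAm-based
    PAI-1 in pg/mL) so effect sizes read in SD units.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zscore requires a 1-D vector of at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zscore undefined for a constant vector")
    return (x - x.mean()) / sd
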