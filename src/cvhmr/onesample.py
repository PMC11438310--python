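"""One-sample Mendelian randomization via two-stage least squares (2SLS).

Stage 1 regresses the exposure on the instrument (plus covariates); stage 2
regresses the outcome on the predicted exposure (plus covariates).  The
reported standard error is the IV-corrected one, computed from structural
residuals ``y - X b`` with the *observed* exposure — the naive stage-2 OLS
standard error (which uses fitted-exposure residuals and is inconsistent)
is kept in the diagnostics for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MrResult
from .instruments import f_statistic

WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    """First-stage F below the conventional strong-instrument threshold."""


def tsls(
    exposure,
    outcome,
    instrument,
    covariates: pd.DataFrame | None = None,
) -> MrResult:
    """Two-stage least-squares causal estimate of exposure on outcome.

    Returns an :class:`MrResult` whose ``beta`` is in outcome units per
    exposure unit, with normal-based 95% CI and two-sided p.  Diagnostics
    carry the first-stage F (a weak instrument, F < 10, sets
    ``weak_instrument`` and emits :class:`WeakInstrumentWarning`), the
    naive stage-2 SE and the first-stage coefficient.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(instrument, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("exposure, outcome and instrument must align")
    if np.ptp(z) == 0:
        raise ValueError("instrument is constant")
    n = x.size
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)

    Z = np.column_stack([np.ones(n), C, z])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("instrument/covariate design is collinear")
    f_stat = f_statistic(x, z, covariates)

    gamma, _, _, _ = np.linalg.lstsq(Z, x, rcond=None)
    x_hat = Z @ gamma

    X_hat = np.column_stack([np.ones(n), C, x_hat])
    if np.linalg.matrix_rank(X_hat) < X_hat.shape[1]:
        raise np.linalg.LinAlgError("second-stage design is collinear")
    b2, _, _, _ = np.linalg.lstsq(X_hat, y, rcond=None)
    beta = float(b2[-1])

    k = X_hat.shape[1]
    xtx_inv_last = np.linalg.inv(X_hat.T @ X_hat)[-1, -1]
    # structural residuals: observed exposure, 2SLS coefficients
    X_obs = np.column_stack([np.ones(n), C, x])
    resid_struct = y - X_obs @ b2
    sigma2 = resid_struct @ resid_struct / (n - k)
    se = float(np.sqrt(sigma2 * xtx_inv_last))
    # naive SE from stage-2 fitted residuals, for reference only
    resid_naive = y - X_hat @ b2
    se_naive = float(np.sqrt(resid_naive @ resid_naive / (n - k) * xtx_inv_last))

    if se > 0:
        zstat = beta / se
        p = float(2 * stats.norm.sf(abs(zstat)))
    else:
        p = 0.0
    half = 1.959963984540054 * se
    weak = f_stat < WEAK_F_THRESHOLD
    if weak:
        warnings.warn(
            f"weak instrument: first-stage F = {f_stat:.2f} < {WEAK_F_THRESHOLD}",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    return MrResult(
        method="2SLS",
        beta=beta,
        se=se,
        ci_low=beta - half,
        ci_high=beta + half,
        p=p,
        n=n,
        diagnostics={
            "first_stage_f": f_stat,
            "weak_instrument": weak,
            "se_naive": se_naive,
            "first_stage_coef": float(gamma[-1]),
        },
    )
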