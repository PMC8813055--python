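"""FRAP normalization and single-exponential recovery fitting.

Raw traces carry ROI, background and unbleached-reference intensities on
an acquisition schedule with a pre-bleach baseline (negative times).
Double normalization divides the background-corrected ROI by the
background-corrected reference (correcting acquisition photobleaching),
rescales by the baseline mean, and re-zeroes at the first post-bleach
frame so the normalized recovery is directly comparable to the model

    F(t) = A (1 - exp(-K t)),

where A is the mobile fraction and tau = 1/K the recovery time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["FrapFit", "normalize_frap", "fit_frap"]


class FrapDataError(ValueError):
    """Inconsistent or physically impossible trace values."""


class FrapFitError(RuntimeError):
    """The nonlinear fit did not converge."""


@dataclass
class FrapFit:
    """Single-exponential recovery fit result."""

    A: float                 # mobile fraction
    K: float                 # rate, 1/min
    tau: float               # 1/K, min
    recovery_at: float | None  # fitted curve value at the reference time
    recovery_time_min: float | None
    rss: float
    converged: bool = True
    message: str = ""


def _model(t, A, K):
    return A * (1.0 - np.exp(-K * t))


def normalize_frap(trace: pd.DataFrame) -> pd.DataFrame:
    """Normalize a raw FRAP trace to the 0-1 recovery scale.

    ``trace`` needs columns ``t_min`` (minutes, baseline negative, first
    post-bleach frame at t >= 0), ``roi``, ``background`` and
    ``reference``.  Returns a frame with columns ``t_min`` and ``F`` for
    the post-bleach samples, where

        I_norm(t) = [(roi - bg) / (ref - bg)] / baseline mean of the ratio
        F(t) = (I_norm(t) - I_norm(0+)) / (1 - I_norm(0+)).
    """
    for col in ("t_min", "roi", "background", "reference"):
        if col not in trace.columns:
            raise ValueError(f"trace is missing column {col!r}")
    t = trace["t_min"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_min must be strictly increasing")
    roi = trace["roi"].to_numpy(float)
    bg = trace["background"].to_numpy(float)
    ref = trace["reference"].to_numpy(float)
    if np.any(ref <= bg):
        raise FrapDataError("reference intensity <= background")
    ratio = (roi - bg) / (ref - bg)
    baseline = ratio[t < 0]
    if len(baseline) == 0:
        raise ValueError("no baseline (t < 0) samples")
    i_norm = ratio / baseline.mean()
    post = t >= 0
    if post.sum() < 3:
        raise ValueError("need >= 3 post-bleach samples")
    i0 = i_norm[post][0]
    if 1.0 - i0 < 1e-6:
        raise FrapDataError("no bleach detected: post-bleach intensity at baseline level")
    F = (i_norm[post] - i0) / (1.0 - i0)
    return pd.DataFrame({"t_min": t[post], "F": F})


def fit_frap(
    normalized: pd.DataFrame,
    recovery_time_min: float | None = None,
) -> FrapFit:
    """Least-squares fit of F(t) = A (1 - exp(-K t)) to a normalized trace.

    A is bounded to [0, 1.5] and K to (0, inf); initial values are the
    last observed value for A and the inverse half-rise time for K.  If
    ``recovery_time_min`` is given (e.g. 10 or 20 min), the fitted curve
    value there is reported as ``recovery_at``.
    """
    t = normalized["t_min"].to_numpy(float)
    F = normalized["F"].to_numpy(float)
    if len(t) < 3:
        raise ValueError("need >= 3 post-bleach points")
    A0 = float(np.clip(F[-1], 1e-3, 1.5))
    half = 0.5 * A0
    above = np.flatnonzero(F >= half)
    t_half = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] / 2 or 1.0)
    K0 = float(np.clip(1.0 / t_half, 1e-4, 1e3))
    if np.allclose(F, 0.0):
        return FrapFit(A=0.0, K=K0, tau=np.inf, recovery_at=0.0 if recovery_time_min else None,
                       recovery_time_min=recovery_time_min, rss=0.0, converged=True,
                       message="identically zero trace")
    try:
        popt, _ = curve_fit(
            _model, t, F, p0=[A0, K0],
            bounds=([0.0, 1e-6], [1.5, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:  # no silent fallback
        return FrapFit(A=np.nan, K=np.nan, tau=np.nan, recovery_at=None,
                       recovery_time_min=recovery_time_min, rss=np.nan,
                       converged=False, message=str(exc))
    A, K = float(popt[0]), float(popt[1])
    resid = F - _model(t, A, K)
    rec = float(_model(np.array([recovery_time_min]), A, K)[0]) if recovery_time_min else None
    return FrapFit(A=A, K=K, tau=1.0 / K, recovery_at=rec,
                   recovery_time_min=recovery_time_min, rss=float(resid @ resid))
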