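"""Detrended-RMS fluctuation statistic for nuclear position tracks.

A slowly drifting track (growth, centering) is detrended by subtracting a
centered running average of window ``W`` frames, so residuals fluctuate
around zero; the amplitude of positional fluctuation is the root mean square
of the residuals. For iid noise of standard deviation sigma the interior
residual variance is sigma^2 (1 - 1/W); any affine trend is removed exactly
at interior points. Fluctuation assays use a 1-min frame interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FluctuationResult", "detrend", "rms", "analyze_fluctuations",
           "compare_rms"]


@dataclass
class FluctuationResult:
    cell_id: str
    window_frames: int
    residuals_um: np.ndarray
    rms_um: float
    frame_interval_min: float


def detrend(x, window: int = 5) -> np.ndarray:
    """Residuals of ``x`` about its centered running average.

    ``window`` must be odd, with 3 <= window <= len(x). At the series edges
    the window shrinks symmetrically to the largest available odd width
    (down to 1, where the residual is 0), so the residual count always
    equals the frame count.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("track must have at least 3 frames")
    if window % 2 == 0 or not 3 <= window <= n:
        raise ValueError("window must be odd and within [3, len(x)]")
    half = window // 2
    trend = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        trend[i] = x[i - h: i + h + 1].mean()
    return x - trend


def rms(residuals) -> float:
    """Root mean square of the residuals (same units as the input)."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residuals")
    return float(np.sqrt(np.mean(r ** 2)))


def analyze_fluctuations(track_x_um, frame_interval_min: float,
                         window: int = 5, cell_id: str = "cell") -> FluctuationResult:
    """Detrend a positional track and report its RMS fluctuation amplitude.

    Warns when the frame interval exceeds 2 min: the statistic is meant for
    the 1-min-interval fluctuation assay, and coarser sampling aliases the
    fluctuations it measures.
    """
    if frame_interval_min > 2.0:
        warnings.warn(
            "fluctuation analysis expects ~1-min frame intervals; "
            f"got {frame_interval_min:g} min", stacklevel=2)
    res = detrend(track_x_um, window)
    return FluctuationResult(cell_id=cell_id, window_frames=window,
                             residuals_um=res, rms_um=rms(res),
                             frame_interval_min=frame_interval_min)


def compare_rms(group_a, group_b):
    """Two-sample, two-tailed t-test on per-movie RMS values.

    Returns ``(statistic, df, p_value)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, len(a) + len(b) - 2, 1.0
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue)
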