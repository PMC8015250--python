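"""Movement statistics: net velocity, direction class, positional ratios,
septum position, growth rate, and the velocity-vs-position regression.

Net nuclear velocity is defined operationally as the change in the distance
from the nucleus center to the *non-growing* cell tip between the first and
last frame, divided by the movie duration (nm/min, positive toward the
growing tip). Slow swelling of non-growing tips therefore leaks into the
estimate as a small apparent velocity; it is deliberately left uncorrected
and reported as measured.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import CellGeometry, GrowthMode, GrowingTip
from .tracking import NuclearTrack, QCFlag

__all__ = [
    "Direction", "MotionSummary", "CenteringMeasurement",
    "LateInterphaseMeasurement", "SeptumMeasurement", "RegressionResult",
    "net_velocity", "classify_direction", "centering_ratio", "ab_ratio",
    "septum_position", "velocity_position_regression", "growth_rate",
]


class Direction(str, enum.Enum):
    TOWARD = "toward"
    STATIONARY = "stationary"
    AWAY = "away"


@dataclass
class MotionSummary:
    cell_id: str
    net_velocity_nm_min: float
    direction: Direction
    d_ng_start_um: float
    d_ng_end_um: float
    duration_min: float
    tip_growth_rate_nm_min: float
    normalized_velocity: float  # net velocity / tip growth rate
    g_start_um: float
    frac_dist_start: float  # g_start / L_start


@dataclass
class CenteringMeasurement:
    s_um: float
    l_um: float

    @property
    def ratio_sl(self) -> float:
        return self.s_um / self.l_um

    @property
    def ratio_s_total(self) -> float:
        return self.s_um / (self.s_um + self.l_um)


@dataclass
class LateInterphaseMeasurement:
    a_um: float  # nucleus -> only-growing (or older-growing) tip
    b_um: float  # nucleus -> other tip

    @property
    def ratio_ab(self) -> float:
        return self.a_um / self.b_um

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.ratio_ab)


@dataclass
class SeptumMeasurement:
    s_um: float
    l_um: float

    @property
    def ratio_s_total(self) -> float:
        return self.s_um / (self.s_um + self.l_um)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def classify_direction(net_displacement_um: float,
                       epsilon: float = 0.25) -> Direction:
    """Direction of net nuclear movement over a movie.

    ``toward`` the growing tip if the displacement exceeds +epsilon (µm),
    ``away`` below -epsilon, otherwise ``stationary``.
    """
    if net_displacement_um > epsilon:
        return Direction.TOWARD
    if net_displacement_um < -epsilon:
        return Direction.AWAY
    return Direction.STATIONARY


def net_velocity(track: NuclearTrack, geometry: CellGeometry,
                 epsilon: float = 0.25, cell_id: str | None = None) -> MotionSummary:
    """Movement summary of a monopolar cell from its track and geometry."""
    if geometry.growth_mode is not GrowthMode.MONOPOLAR:
        raise ValueError(f"net velocity requires monopolar growth, "
                         f"got {geometry.growth_mode.value}")
    ok = [i for i, f in enumerate(track.qc_flag) if f is QCFlag.OK]
    if len(ok) < 2:
        raise ValueError("need at least 2 unflagged frames")
    first, last = ok[0], ok[-1]
    duration = float(track.t_min[last] - track.t_min[first])
    d0 = float(track.d_ng_um[first])
    d1 = float(track.d_ng_um[last])
    vel = 1000.0 * (d1 - d0) / duration
    gr = growth_rate(geometry)
    g0 = float(track.d_g_um[first])
    L0 = float(geometry.length_um[first])
    return MotionSummary(
        cell_id=cell_id or track.cell_id,
        net_velocity_nm_min=vel,
        direction=classify_direction(d1 - d0, epsilon),
        d_ng_start_um=d0,
        d_ng_end_um=d1,
        duration_min=duration,
        tip_growth_rate_nm_min=gr,
        normalized_velocity=vel / gr if gr > 0 else float("nan"),
        g_start_um=g0,
        frac_dist_start=g0 / L0,
    )


def centering_ratio(x_um: float, tip_a_um: float, tip_b_um: float) -> CenteringMeasurement:
    """Shorter/longer nucleus-to-tip distances for one frame (s/l = 1 when
    perfectly centered)."""
    da, db = abs(x_um - tip_a_um), abs(x_um - tip_b_um)
    s, l = min(da, db), max(da, db)
    if s <= 0:
        raise ValueError("nucleus coincides with a cell tip")
    return CenteringMeasurement(s_um=s, l_um=l)


def ab_ratio(x_um: float, tip_ref_um: float, tip_other_um: float) -> LateInterphaseMeasurement:
    """Late-interphase position ratio a/b.

    ``a`` is the distance to the reference tip (the only-growing tip of a
    monopolar cell, or the older-growing tip of a bipolar cell, supplied by
    the caller), ``b`` to the other tip. Group statistics should be computed
    on ``log2_ratio``.
    """
    a = abs(x_um - tip_ref_um)
    b = abs(x_um - tip_other_um)
    if a <= 0 or b <= 0:
        raise ValueError("nucleus coincides with a cell tip")
    return LateInterphaseMeasurement(a_um=a, b_um=b)


def septum_position(frame: np.ndarray, geometry: CellGeometry,
                    frame_index: int = 0, nucleus_x_um: float | None = None,
                    central_fraction: float = 0.6,
                    min_contrast: float = 1.5) -> SeptumMeasurement:
    """Locate the septum and measure its position between the tips.

    The septum is the axial position maximizing the mean perpendicular
    intensity within the central ``central_fraction`` of the cell, excluding
    the nucleus region when ``nucleus_x_um`` is given. The peak must exceed
    ``min_contrast`` times the median profile level, else ``LookupError``
    ("no septum"). The peak is refined to sub-pixel by a parabolic fit.
    """
    mask = geometry.masks[frame_index]
    img = np.asarray(frame, dtype=float)
    counts = mask.sum(axis=1)
    sums = np.where(mask, img, 0.0).sum(axis=1)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    tip_a = geometry.tip_a_um[frame_index]
    tip_b = geometry.tip_b_um[frame_index]
    lo_um = min(tip_a, tip_b) + (1 - central_fraction) / 2 * abs(tip_b - tip_a)
    hi_um = max(tip_a, tip_b) - (1 - central_fraction) / 2 * abs(tip_b - tip_a)
    rows = np.arange(len(profile))
    ax = geometry.axial_of_row(rows)
    valid = (ax >= lo_um) & (ax <= hi_um) & ~np.isnan(profile)
    if nucleus_x_um is not None:
        valid &= np.abs(ax - nucleus_x_um) > 1.5  # exclude the nuclear disk
    if not valid.any():
        raise LookupError("no septum: empty search window")
    base = float(np.nanmedian(profile[valid]))
    idx = np.where(valid)[0]
    peak = idx[np.nanargmax(profile[idx])]
    if profile[peak] < min_contrast * base:
        raise LookupError("no septum: no band above threshold")
    # parabolic sub-pixel refinement
    r = float(peak)
    if 0 < peak < len(profile) - 1 and not np.isnan(profile[peak - 1]) \
            and not np.isnan(profile[peak + 1]):
        y0, y1, y2 = profile[peak - 1], profile[peak], profile[peak + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            r = peak + 0.5 * (y0 - y2) / denom
    sep = float(geometry.axial_of_row(r))
    da, db = abs(sep - tip_a), abs(sep - tip_b)
    return SeptumMeasurement(s_um=min(da, db), l_um=max(da, db))


def velocity_position_regression(frac_dist_start, net_velocity_nm_min) -> RegressionResult:
    """OLS of net velocity on fractional nucleus-to-growing-tip distance.

    r² is the squared Pearson correlation; the p-value is the two-sided t
    test of zero slope with n-2 degrees of freedom.
    """
    x = np.asarray(frac_dist_start, dtype=float)
    y = np.asarray(net_velocity_nm_min, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs at least 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    if np.ptp(y) == 0:  # flat response: slope 0, no explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0,
                                p_value=1.0, n=len(x))
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                            n=len(x))


def growth_rate(geometry: CellGeometry) -> float:
    """Tip growth rate (nm/min): least-squares slope of the growing-tip
    coordinate against time."""
    if geometry.growth_mode not in (GrowthMode.MONOPOLAR, GrowthMode.NONE):
        raise ValueError("growth rate is defined per single growing tip")
    n = len(geometry.tip_a_um)
    if n < 2:
        raise ValueError("need at least 2 frames")
    t = np.arange(n) * geometry.frame_interval
    tip = geometry.tip_g_um if geometry.growing_tip is not GrowingTip.NONE \
        else geometry.tip_b_um
    slope = np.polyfit(t, tip, 1)[0]
    return float(1000.0 * slope)
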