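"""Cell segmentation, long-axis orientation, tip tracking, growth-mode calls.

The analysis works in a 1D axial coordinate along the cell's long axis:
origin at the frame-0 non-growing tip, positive toward the growing tip (µm).
Tips are localized per frame to sub-pixel precision from the blurred edge
profile along the axis, so that per-frame cell lengths and nucleus-to-tip
distances are not quantized to whole pixels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .stack import TimeLapseStack

__all__ = ["GrowthMode", "GrowingTip", "CellGeometry", "segment_cell",
           "fit_long_axis", "rotate_vertical", "track_tips", "analyze_geometry"]


class GrowthMode(str, enum.Enum):
    MONOPOLAR = "monopolar"
    BIPOLAR = "bipolar"
    NONE = "none"


class GrowingTip(str, enum.Enum):
    TIP_A = "tip_A"  # top of the rotated frame (smaller row)
    TIP_B = "tip_B"  # bottom of the rotated frame (larger row)
    BOTH = "both"
    NONE = "none"


@dataclass
class CellGeometry:
    """Per-frame cell geometry in axis coordinates.

    ``tip_a_um`` / ``tip_b_um`` are the axial coordinates (µm) of the two
    cell tips per frame, with the origin fixed at the frame-0 non-growing
    tip and the sign chosen so the growing tip is positive. ``origin_row``
    and ``axis_sign`` record the row <-> µm mapping of the rotated stack:
    axial_um = axis_sign * (row - origin_row) * pixel_size.
    """

    masks: np.ndarray  # T x Y x X bool
    axis_angle: float  # degrees from the image column axis, frame 0
    tip_a_um: np.ndarray
    tip_b_um: np.ndarray
    growing_tip: GrowingTip
    growth_mode: GrowthMode
    pixel_size: float
    frame_interval: float
    origin_row: float
    axis_sign: int
    axis_col: float  # column of the cell axis in the rotated frame

    @property
    def length_um(self) -> np.ndarray:
        return np.abs(self.tip_a_um - self.tip_b_um)

    @property
    def tip_ng_um(self) -> np.ndarray:
        """Non-growing tip coordinate per frame (monopolar cells)."""
        if self.growing_tip is GrowingTip.TIP_A:
            return self.tip_b_um
        return self.tip_a_um

    @property
    def tip_g_um(self) -> np.ndarray:
        """Growing tip coordinate per frame (monopolar cells)."""
        if self.growing_tip is GrowingTip.TIP_A:
            return self.tip_a_um
        return self.tip_b_um

    def axial_of_row(self, row):
        return self.axis_sign * (np.asarray(row, dtype=float) - self.origin_row) \
            * self.pixel_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.tip_a_um)),
            "tipA_um": self.tip_a_um,
            "tipB_um": self.tip_b_um,
            "length_um": self.length_um,
            "growing_tip": self.growing_tip.value,
            "growth_mode": self.growth_mode.value,
        })


def segment_cell(frame: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Binary cell mask: Gaussian smooth, Otsu threshold, largest component,
    holes filled.

    Frames with a tip+nucleus reporter have three intensity tiers
    (background, cytoplasm, nucleus/cap), so a three-class Otsu is tried
    first and its lowest threshold taken (background vs cell); plain
    two-class Otsu is the fallback for bimodal frames. Raises if the mask is
    empty or the cell is cropped (touches three or more image borders).
    """
    img = ndimage.gaussian_filter(np.asarray(frame, dtype=float), smooth_sigma)
    if img.max() <= img.min():
        raise ValueError("empty mask: frame has no contrast")
    try:
        thr = filters.threshold_multiotsu(img, classes=3)[0]
    except ValueError:
        thr = filters.threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        raise ValueError("empty mask")
    labels = measure.label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    mask = ndimage.binary_fill_holes(mask)
    borders = [mask[0].any(), mask[-1].any(), mask[:, 0].any(), mask[:, -1].any()]
    if sum(borders) >= 3:
        raise ValueError("cell cropped: mask touches >= 3 image borders")
    return mask


def fit_long_axis(mask: np.ndarray, min_aspect: float = 1.2):
    """Principal-axis orientation of a binary mask.

    Returns ``(angle_deg, endpoints)``: the angle of the major axis measured
    from the image column (horizontal) axis in degrees, in [-90, 90), and the
    two extremal mask pixels along that axis as (row, col) pairs. Raises for
    near-isotropic masks (aspect ratio below ``min_aspect``).
    """
    coords = np.argwhere(mask).astype(float)
    if coords.size == 0:
        raise ValueError("empty mask")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0 or np.sqrt(evals[1] / max(evals[0], 1e-12)) < min_aspect:
        raise ValueError("no long axis: mask is near-isotropic")
    v = evecs[:, 1]  # (d_row, d_col) of the major axis
    angle = np.degrees(np.arctan2(v[0], v[1]))
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    proj = centered @ v
    endpoints = (tuple(coords[proj.argmin()]), tuple(coords[proj.argmax()]))
    return float(angle), endpoints


def rotate_vertical(stack: TimeLapseStack, angle: float) -> TimeLapseStack:
    """Rotate every frame so the fitted long axis becomes vertical.

    ``angle`` is the output of :func:`fit_long_axis` on a frame of this
    stack. Bilinear interpolation about the image center, expanded canvas,
    out-of-frame pixels filled with the frame's median intensity.
    """
    rot = (angle - 90.0) % 180.0  # map the axis onto the row direction ...
    if rot > 90.0:
        rot -= 180.0  # ... by the smaller of the two equivalent rotations
    frames = stack.frames.astype(float)
    out = [ndimage.rotate(f, rot, reshape=True, order=1, mode="constant",
                          cval=float(np.median(f))) for f in frames]
    return replace(stack, frames=np.clip(np.stack(out), 0, None))


def register_static_pole(stack: TimeLapseStack):
    """Translation registration anchored on the cell's static pole.

    Phase correlation mis-registers single-cell movies: with one growing
    cell and a featureless background, tip growth is itself the dominant
    image motion and gets absorbed into the estimated translation. For
    single-cell crops the operative criterion is instead that the cell is
    stationary in real space apart from its growing tip(s): each frame is
    shifted so that the cell edge with the smallest net axial displacement
    (the static pole) and the lateral mask centroid stay fixed at their
    frame-0 positions.

    Returns ``(registered_stack, shifts)``; ``shifts`` columns are
    (frame, dy_px, dx_px), the estimated displacement of each frame.
    Lateral (column) shifts are applied with bilinear interpolation at
    sub-pixel precision; axial (row) shifts are integer pixel counts taken
    from the mask extent, so tip swelling and growth inside the frame are
    preserved as measured.
    """
    from .stack import TimeLapseStack as _TLS  # noqa: F401  (doc aid)
    if stack.has_z:
        raise ValueError("register after Z projection")
    T = stack.n_frames
    tops = np.empty(T)
    bots = np.empty(T)
    cols = np.empty(T)
    for i, frame in enumerate(stack.frames):
        mask = segment_cell(frame)
        rr = np.where(mask.any(axis=1))[0]
        tops[i], bots[i] = rr[0], rr[-1]
        cols[i] = np.argwhere(mask)[:, 1].mean()
    d_top = tops - tops[0]
    d_bot = bots - bots[0]
    # the static pole is the edge with the smaller net displacement
    dy = d_top if abs(d_top[-1]) <= abs(d_bot[-1]) else d_bot
    dx = cols - cols[0]
    out = np.empty_like(stack.frames, dtype=float)
    rows = []
    for i, frame in enumerate(stack.frames):
        f = frame.astype(float)
        shift = (-float(dy[i]), -float(dx[i]) if abs(dx[i]) > 0.25 else 0.0)
        if any(shift):
            f = ndimage.shift(f, shift, order=1, mode="constant",
                              cval=float(np.median(f)))
        out[i] = f
        rows.append({"frame": i, "dy_px": float(dy[i]), "dx_px": float(dx[i])})
    registered = replace(stack, frames=np.clip(out, 0, None))
    return registered, pd.DataFrame(rows)


def _tip_rows_subpixel(frame: np.ndarray, mask: np.ndarray,
                       plateau_inset: tuple[int, int] = (6, 18)) -> tuple[float, float]:
    """Sub-pixel (top_row, bottom_row) of a vertically oriented cell.

    Uses the intensity profile averaged over the 5 columns around the cell
    axis; each tip is the half-maximum crossing of the blurred edge, with the
    plateau estimated just inside that tip (so the bright tip cap does not
    bias the crossing) and the background just outside the cell.
    """
    rows_any = np.where(mask.any(axis=1))[0]
    if rows_any.size == 0:
        raise ValueError("empty mask")
    cols = np.where(mask.any(axis=0))[0]
    c = int(round(cols.mean()))
    c0, c1 = max(c - 2, 0), min(c + 3, frame.shape[1])
    prof = np.asarray(frame, dtype=float)[:, c0:c1].mean(axis=1)

    r_top, r_bot = int(rows_any[0]), int(rows_any[-1])
    outside = np.r_[prof[: max(r_top - 4, 0)], prof[r_bot + 5:]]
    bg = float(np.median(outside)) if outside.size else float(prof.min())

    def crossing(r_edge: int, direction: int) -> float:
        a, b = plateau_inset
        sl = prof[r_edge + direction * a: r_edge + direction * b: direction]
        plateau = float(np.median(sl)) if sl.size else float(prof[r_edge])
        half = bg + 0.5 * (plateau - bg)
        # start just inside the edge; step further inside if the mask edge
        # sits below the half-maximum, then scan outward to the crossing
        i = r_edge + direction * 2
        i = min(max(i, 0), len(prof) - 1)
        while 0 <= i < len(prof) and prof[i] < half:
            i += direction
        while 0 <= i < len(prof) and prof[i] >= half:
            i -= direction
        j = i + direction  # prof[j] >= half > prof[i]
        if not (0 <= i < len(prof)):
            return float(r_edge)
        denom = prof[j] - prof[i]
        frac = (half - prof[i]) / denom if denom != 0 else 0.5
        return float(i + direction * frac)

    return crossing(r_top, +1), crossing(r_bot, -1)


def track_tips(masks: np.ndarray, frames: np.ndarray | None = None,
               pixel_size: float = 0.10, theta_grow: float = 0.5):
    """Locate both tips per frame and classify the growth mode.

    ``masks`` is T x Y x X (vertically oriented cell); ``frames`` supplies
    intensities for sub-pixel edge localization (falls back to mask extents
    when omitted). A tip is growing when its net outward displacement over
    the movie exceeds ``theta_grow`` (µm): exactly one growing tip is
    monopolar, two bipolar (including the equal-displacement tie), zero none.

    Returns ``(rows_top, rows_bot, growing_tip, growth_mode)`` with rows in
    fractional pixels. Raises if tip identity cannot be tracked (frame-to-
    frame tip displacement larger than half the cell length).
    """
    T = masks.shape[0]
    rows_top = np.empty(T)
    rows_bot = np.empty(T)
    for i in range(T):
        if frames is not None:
            rows_top[i], rows_bot[i] = _tip_rows_subpixel(frames[i], masks[i])
        else:
            rr = np.where(masks[i].any(axis=1))[0]
            rows_top[i], rows_bot[i] = float(rr[0]), float(rr[-1])
        if i:
            half_len = 0.5 * (rows_bot[i] - rows_top[i])
            if (abs(rows_top[i] - rows_top[i - 1]) > half_len
                    or abs(rows_bot[i] - rows_bot[i - 1]) > half_len):
                raise ValueError("tip tracking failure: tip identity swap")

    disp_top = (rows_top[0] - rows_top[-1]) * pixel_size  # outward = up
    disp_bot = (rows_bot[-1] - rows_bot[0]) * pixel_size  # outward = down
    grow_top = disp_top > theta_grow
    grow_bot = disp_bot > theta_grow
    if grow_top and grow_bot:
        growing, mode = GrowingTip.BOTH, GrowthMode.BIPOLAR
    elif grow_top:
        growing, mode = GrowingTip.TIP_A, GrowthMode.MONOPOLAR
    elif grow_bot:
        growing, mode = GrowingTip.TIP_B, GrowthMode.MONOPOLAR
    else:
        growing, mode = GrowingTip.NONE, GrowthMode.NONE
    return rows_top, rows_bot, growing, mode


def analyze_geometry(rotated: TimeLapseStack, theta_grow: float = 0.5) -> CellGeometry:
    """Full per-frame geometry of a vertically oriented, registered stack."""
    masks = np.stack([segment_cell(f) for f in rotated.frames])
    rows_top, rows_bot, growing, mode = track_tips(
        masks, rotated.frames, rotated.pixel_size, theta_grow)
    angle, _ = fit_long_axis(masks[0])

    # axis coordinate: origin at the frame-0 non-growing tip, growing tip positive.
    if growing is GrowingTip.TIP_A:  # grows upward: decreasing row = positive axial
        origin_row, sign = rows_bot[0], -1
    else:  # default orientation: tip_B (bottom) growing, or ambiguous modes
        origin_row, sign = rows_top[0], +1
    tip_a = sign * (rows_top - origin_row) * rotated.pixel_size
    tip_b = sign * (rows_bot - origin_row) * rotated.pixel_size
    cols = np.where(masks[0].any(axis=0))[0]
    return CellGeometry(
        masks=masks, axis_angle=angle, tip_a_um=tip_a, tip_b_um=tip_b,
        growing_tip=growing, growth_mode=mode, pixel_size=rotated.pixel_size,
        frame_interval=rotated.frame_interval, origin_row=float(origin_row),
        axis_sign=sign, axis_col=float(cols.mean()),
    )
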