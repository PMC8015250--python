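"""Per-frame nuclear segmentation and sub-pixel centroid tracking.

The nucleus is the brightest large structure inside the cell away from the
tip caps (the tip reporter also labels the nucleus, artifactually but
usefully). Positions are reported in the 1D axial coordinate defined by
:class:`nucleodrift.geometry.CellGeometry`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .geometry import CellGeometry
from .stack import TimeLapseStack

__all__ = ["QCFlag", "NuclearTrack", "segment_nucleus", "nucleus_centroid",
           "build_track"]


class QCFlag(str, enum.Enum):
    OK = "ok"
    LOW_CONTRAST = "low_contrast"
    JUMP = "jump"


@dataclass
class NuclearTrack:
    """Sub-pixel nuclear positions of one cell in axis coordinates (µm)."""

    t_min: np.ndarray
    centroid_px: np.ndarray  # T x 2 (row, col); NaN where interpolated
    x_um: np.ndarray  # axial position, origin at frame-0 non-growing tip
    d_ng_um: np.ndarray  # distance to the non-growing tip
    d_g_um: np.ndarray  # distance to the growing tip (g)
    qc_flag: list
    cell_id: str = "cell"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_id,
            "frame": np.arange(len(self.t_min)),
            "t_min": self.t_min,
            "x_um": self.x_um,
            "d_ng_um": self.d_ng_um,
            "d_g_um": self.d_g_um,
            "qc_flag": [f.value for f in self.qc_flag],
        })


def segment_nucleus(frame: np.ndarray, cell_mask: np.ndarray,
                    geometry: CellGeometry, frame_index: int = 0,
                    d_cap: float = 1.5) -> np.ndarray:
    """Nucleus mask: Otsu inside the cell, tip-cap components excluded.

    Thresholds the intensities inside the cell mask, then among the bright
    components keeps the largest whose centroid lies more than ``d_cap`` µm
    from both tips (axially), rejecting the bright cap at the growing tip.
    Raises ``LookupError`` when no component qualifies (low contrast).
    """
    vals = np.asarray(frame, dtype=float)[cell_mask]
    if vals.max() <= vals.min():
        raise LookupError("low contrast: uniform intensities inside the cell")
    thr = filters.threshold_otsu(vals)
    bright = (frame > thr) & cell_mask
    labels = measure.label(bright)
    tip_a = geometry.tip_a_um[frame_index]
    tip_b = geometry.tip_b_um[frame_index]
    best, best_area = None, 0
    for region in measure.regionprops(labels):
        ax = float(geometry.axial_of_row(region.centroid[0]))
        if min(abs(ax - tip_a), abs(ax - tip_b)) <= d_cap:
            continue
        if region.area > best_area:
            best, best_area = region.label, region.area
    if best is None:
        raise LookupError("low contrast: no nuclear component away from the tips")
    return labels == best


def nucleus_centroid(frame: np.ndarray, nucleus_mask: np.ndarray,
                     cell_mask: np.ndarray | None = None,
                     weighted: bool = True) -> tuple[float, float]:
    """Sub-pixel (row, col) centroid of the nucleus.

    Intensity-weighted over the nucleus mask after subtracting the local
    background (median intensity of the cell mask outside the nucleus);
    ``weighted=False`` gives the plain binary-mask centroid.
    """
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    coords = np.argwhere(nucleus_mask).astype(float)
    if not weighted:
        r, c = coords.mean(axis=0)
        return float(r), float(c)
    img = np.asarray(frame, dtype=float)
    if cell_mask is not None:
        outside = cell_mask & ~nucleus_mask
        bg = float(np.median(img[outside])) if outside.any() else 0.0
    else:
        bg = 0.0
    w = np.clip(img[nucleus_mask] - bg, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight after background subtraction")
    r, c = (coords * w[:, None]).sum(axis=0) / total
    return float(r), float(c)


def build_track(stack: TimeLapseStack, geometry: CellGeometry,
                d_cap: float = 1.5, max_jump: float = 1.0,
                max_flagged_fraction: float = 0.2,
                weighted: bool = True, cell_id: str = "cell") -> NuclearTrack:
    """Track the nuclear centroid through a rotated, registered stack.

    Per frame: segment the nucleus, take its sub-pixel centroid, project the
    row onto the cell axis (µm). Frames where segmentation fails are flagged
    ``low_contrast``; frames whose displacement from the previous accepted
    position exceeds ``max_jump`` (µm) are flagged ``jump``. Flagged frames
    are filled by linear interpolation of the axial position. The track is
    rejected when more than ``max_flagged_fraction`` of frames are flagged.
    """
    T = stack.n_frames
    cent = np.full((T, 2), np.nan)
    x = np.full(T, np.nan)
    flags = [QCFlag.OK] * T
    last_good = None
    for i in range(T):
        try:
            nmask = segment_nucleus(stack.frames[i], geometry.masks[i],
                                    geometry, i, d_cap)
            r, c = nucleus_centroid(stack.frames[i], nmask, geometry.masks[i],
                                    weighted=weighted)
        except (LookupError, ValueError):
            flags[i] = QCFlag.LOW_CONTRAST
            continue
        xi = float(geometry.axial_of_row(r))
        if last_good is not None and abs(xi - last_good) > max_jump:
            flags[i] = QCFlag.JUMP
            continue
        cent[i] = (r, c)
        x[i] = xi
        last_good = xi

    flagged = np.isnan(x)
    if flagged.all():
        raise ValueError("track rejected: no usable frames")
    if flagged.mean() > max_flagged_fraction:
        raise ValueError(
            f"track rejected: {flagged.mean():.0%} of frames flagged")
    if flagged.any():
        good = np.where(~flagged)[0]
        x[flagged] = np.interp(np.where(flagged)[0], good, x[good])

    tip_ng = geometry.tip_ng_um
    tip_g = geometry.tip_g_um
    return NuclearTrack(
        t_min=stack.times_min,
        centroid_px=cent,
        x_um=x,
        d_ng_um=np.abs(x - tip_ng),
        d_g_um=np.abs(tip_g - x),
        qc_flag=flags,
        cell_id=cell_id,
    )
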