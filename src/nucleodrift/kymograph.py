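"""Wide-line kymographs: time vs axial position, resliced along the cell axis.

For each frame, intensity is sampled at unit-pixel steps along a line
spanning the cell's long axis; at every step the sample is the mean (or max)
of ``width_px`` bilinearly interpolated samples taken perpendicular to the
line. One kymograph row per frame.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage

from .stack import TimeLapseStack

__all__ = ["Kymograph", "make_kymograph", "write_kymograph"]


@dataclass
class Kymograph:
    image: np.ndarray  # T x Npos
    width_px: int
    pixel_size: float  # µm per column
    frame_interval: float  # min per row

    @property
    def n_frames(self) -> int:
        return self.image.shape[0]


def make_kymograph(stack: TimeLapseStack, start: tuple[float, float],
                   end: tuple[float, float], width_px: int = 11,
                   aggregate: str = "mean") -> Kymograph:
    """Reslice a stack along the line ``start`` -> ``end`` ((row, col) px).

    ``width_px`` must be odd; perpendicular offsets run from -(width_px//2)
    to +(width_px//2). ``aggregate`` is ``"mean"`` or ``"max"``.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd integer")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    if stack.has_z:
        raise ValueError("project Z before reslicing")
    r0, c0 = map(float, start)
    r1, c1 = map(float, end)
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise ValueError("degenerate axis line")
    n_pos = int(np.floor(length)) + 1
    ur, uc = (r1 - r0) / length, (c1 - c0) / length  # unit vector along line
    pr, pc = -uc, ur  # unit perpendicular
    half = width_px // 2

    steps = np.arange(n_pos)
    offsets = np.arange(-half, half + 1)
    rows = r0 + steps[:, None] * ur + offsets[None, :] * pr  # n_pos x width
    cols = c0 + steps[:, None] * uc + offsets[None, :] * pc
    H, W = stack.frames.shape[-2:]
    if rows.min() < -0.5 or rows.max() > H - 0.5 or \
            cols.min() < -0.5 or cols.max() > W - 0.5:
        raise ValueError("reslice line exits image bounds")
    coords = np.stack([rows.ravel(), cols.ravel()])

    out = np.empty((stack.n_frames, n_pos))
    for i, frame in enumerate(stack.frames):
        samples = ndimage.map_coordinates(
            np.asarray(frame, dtype=float), coords, order=1, mode="nearest"
        ).reshape(n_pos, width_px)
        out[i] = samples.mean(axis=1) if aggregate == "mean" else samples.max(axis=1)

    return Kymograph(image=out, width_px=width_px,
                     pixel_size=stack.pixel_size,
                     frame_interval=stack.frame_interval)


def write_kymograph(kymo: Kymograph, path) -> None:
    """Write the kymograph as a single-page 32-bit TIFF plus a calibration
    sidecar (same path with suffix ``.txt``)."""
    path = pathlib.Path(path)
    tifffile.imwrite(path, kymo.image.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".txt")
    sidecar.write_text(
        f"width_px: {kymo.width_px}\n"
        f"axial_calibration_um_per_px: {kymo.pixel_size}\n"
        f"time_calibration_min_per_row: {kymo.frame_interval}\n"
    )
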