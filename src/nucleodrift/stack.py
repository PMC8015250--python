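"""Calibrated time-lapse stacks: TIFF I/O, Z projection, X/Y registration."""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = ["TimeLapseStack", "load_stack", "write_stack", "max_project",
           "register_translation"]


@dataclass
class TimeLapseStack:
    """Image sequence with spatial and temporal calibration.

    ``frames`` is T x Y x X (or T x Z x Y x X for unprojected data);
    ``pixel_size`` in µm/px, ``frame_interval`` in min.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    provenance: str = "unknown"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be TxYxX or TxZxYxX")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if np.issubdtype(self.frames.dtype, np.floating) and (self.frames < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def has_z(self) -> bool:
        return self.frames.ndim == 4

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def load_stack(path, pixel_size: float, frame_interval: float,
               n_z: int | None = None) -> TimeLapseStack:
    """Read a multi-page TIFF as a calibrated stack (page order = time).

    ``n_z`` reshapes a flat page sequence into T x Z x Y x X when the file
    interleaves Z-sections within each time point.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if n_z is not None and frames.ndim == 3:
        if frames.shape[0] % n_z:
            raise ValueError("page count is not a multiple of n_z")
        frames = frames.reshape(-1, n_z, *frames.shape[1:])
    return TimeLapseStack(frames=frames, pixel_size=pixel_size,
                          frame_interval=frame_interval, provenance=str(path))


def write_stack(stack: TimeLapseStack, path) -> None:
    tifffile.imwrite(path, stack.frames)


def max_project(stack: TimeLapseStack) -> TimeLapseStack:
    """Maximum projection over Z (pixelwise), calibration preserved."""
    if not stack.has_z:
        raise ValueError("stack is already 2D (no Z axis to project)")
    return replace(stack, frames=stack.frames.max(axis=1))


def register_translation(stack: TimeLapseStack, upsample_factor: int = 50):
    """Align every frame to frame 0 by phase-correlation translation.

    Sub-pixel shifts are estimated with upsampled cross-correlation and
    applied with bilinear interpolation; pixels shifted in from outside the
    frame are filled with that frame's median (background) intensity.
    Blank frames (zero variance) get the identity shift.

    Returns ``(registered_stack, shifts)`` where ``shifts`` is a DataFrame
    with columns (frame, dy_px, dx_px, blank): the estimated displacement of
    each frame relative to frame 0.
    """
    if stack.has_z:
        raise ValueError("register after Z projection")
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = stack.frames[0].astype(float)
    out = np.empty_like(stack.frames, dtype=float)
    out[0] = ref
    rows = [{"frame": 0, "dy_px": 0.0, "dx_px": 0.0, "blank": False}]
    for i in range(1, stack.n_frames):
        frame = stack.frames[i].astype(float)
        blank = float(frame.std()) == 0.0
        if blank:
            shift = np.zeros(2)
        else:
            shift, _err, _phase = phase_cross_correlation(
                ref, frame, upsample_factor=upsample_factor, normalization=None)
        if np.any(shift):
            out[i] = ndimage.shift(frame, shift, order=1, mode="constant",
                                   cval=float(np.median(frame)))
        else:
            out[i] = frame
        rows.append({"frame": i, "dy_px": -float(shift[0]),
                     "dx_px": -float(shift[1]), "blank": blank})
    registered = replace(stack, frames=np.clip(out, 0, None))
    return registered, pd.DataFrame(rows)
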