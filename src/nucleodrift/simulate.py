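"""Synthetic time-lapse generation for nuclear-movement assays.

Simulates 1D nuclear trajectories in a growing rod-shaped (fission-yeast-like)
cell under several phenomenological motion regimes, and renders them as noisy
fluorescence time-lapse stacks that mimic a tip+nucleus reporter (bright caps
at growing tips, a bright nuclear disk, dimmer cytoplasm).

Motion regimes
--------------
``wt_dmso``
    Microtubules present: a linear restoring force centers the nucleus on the
    instantaneous cell midpoint (Ornstein-Uhlenbeck dynamics around a moving
    target), drift = -k (x - L(t)/2).
``wt_mbc``
    Microtubules depolymerized: tip-directed drift whose strength decays with
    the distance ``g`` from the nucleus to the growing tip,
    v(g) = vmax * exp(-g / lam). Capped at the tip growth rate by construction
    (vmax <= vg).
``cable_null_mbc``
    No actin cables, no microtubules: zero drift; the nucleus only diffuses.
``myo52_mbc``
    Drift alternates between the ``wt_mbc`` law and an aberrant state (zero or
    reversed drift) via a two-state Markov switch, reproducing intermittent
    stalls and reversals.

All regimes share tip growth (L(t) = L0 + vg*t), slow apparent extension of
the non-growing tip (the "tip swelling" measurement artifact), additive
Gaussian diffusion of amplitude sigma, and reflecting confinement of the
nucleus to the cell interior.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "Mode",
    "SimulationConfig",
    "GroundTruthTrajectory",
    "RenderParams",
    "simulate_trajectory",
    "render_stack",
    "generate_cohort",
    "TRUTH_COLUMNS",
]


class Mode(str, enum.Enum):
    """Simulated genotype/treatment regime."""

    WT_DMSO = "wt_dmso"
    WT_MBC = "wt_mbc"
    CABLE_NULL_MBC = "cable_null_mbc"
    MYO52_MBC = "myo52_mbc"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the 1D nuclear-motion model.

    Lengths in µm, times in min. The axial origin is the position of the
    non-growing tip at t=0; the growing tip starts at ``L0``.

    Attributes
    ----------
    mode : Mode or str
        Motion regime (see module docstring).
    L0 : float
        Initial cell length (µm).
    x0 : float
        Initial nuclear axial position (µm from the non-growing tip).
    vg : float
        Tip growth rate (µm/min). ~0.02-0.04 µm/min at 25 °C.
    k : float
        Centering strength (1/min) of the restoring force in ``wt_dmso``.
    sigma : float
        Diffusion amplitude (µm/min^0.5).
    vmax : float
        Maximal tip-directed drift (µm/min); must not exceed ``vg``.
    lam : float
        Decay length (µm) of the drift law v(g)=vmax*exp(-g/lam). The default
        is calibrated so that v(g)=0.012 µm/min (12 nm/min) when the nucleus
        sits 5.5 µm from the growing tip (the center of a full-grown ~11 µm
        cell), matching the observed net tip-directed velocity.
    swell_rate : float
        Apparent outward extension of the non-growing tip (µm/min). Models
        the slow swelling/shape change at non-growing tips that produces
        small apparent velocities in the uncorrected estimator.
    reversal_rates : (float, float)
        Markov switching rates (1/min) between normal-drift and aberrant
        states in ``myo52_mbc``: (on->aberrant, aberrant->on).
    duration : float
        Movie duration (min); must be an integer multiple of ``dt``.
    dt : float
        Frame interval (min): 5 for movement assays, 1 for fluctuation assays.
    seed : int
        Seed for the trajectory noise (and the Markov switch).
    margin : float
        Confinement margin (µm): the nucleus center stays at least this far
        from either tip (defaults to the rendered nuclear radius).
    """

    mode: Mode = Mode.WT_MBC
    L0: float = 9.5
    x0: float = 4.75
    vg: float = 0.03
    k: float = 0.05
    sigma: float = 0.03
    vmax: float = 0.03
    lam: float = 6.0
    swell_rate: float = 0.002
    reversal_rates: tuple[float, float] = (0.05, 0.05)
    duration: float = 90.0
    dt: float = 5.0
    seed: int = 0
    margin: float = 1.2

    def __post_init__(self):
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        if self.vg < 0:
            raise ValueError("tip growth rate vg must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (0 < self.x0 < self.L0):
            raise ValueError("initial nuclear position x0 must lie inside the cell")
        if self.vmax > self.vg + 1e-12:
            raise ValueError("drift vmax may not exceed the tip growth rate vg")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer multiple of dt")

    @property
    def n_frames(self) -> int:
        """Number of frames, including t=0."""
        return int(round(self.duration / self.dt)) + 1


@dataclass
class GroundTruthTrajectory:
    """Per-frame ground truth of one simulated cell.

    Arrays are indexed by frame; ``drift_applied[i]`` is the deterministic
    drift (µm/min) used in the Euler-Maruyama step taken *from* frame i
    (zero for the last frame).
    """

    config: SimulationConfig
    t: np.ndarray  # min
    L: np.ndarray  # cell length, µm
    tip_ng: np.ndarray  # non-growing tip coordinate, µm
    tip_g: np.ndarray  # growing tip coordinate, µm
    x: np.ndarray  # nuclear axial position, µm
    drift_applied: np.ndarray  # µm/min

    @property
    def g(self) -> np.ndarray:
        """Distance from nucleus to the growing tip (µm), per frame."""
        return self.tip_g - self.x

    @property
    def d_ng(self) -> np.ndarray:
        """Distance from nucleus to the non-growing tip (µm), per frame."""
        return self.x - self.tip_ng

    @property
    def frac_dist_start(self) -> float:
        """Initial nucleus-to-growing-tip distance as a fraction of cell length."""
        return float(self.g[0] / self.L[0])

    @property
    def net_displacement(self) -> float:
        """Change of the nucleus-to-non-growing-tip distance over the movie (µm)."""
        return float(self.d_ng[-1] - self.d_ng[0])

    @property
    def net_velocity_nm_min(self) -> float:
        """Net velocity toward the growing tip (nm/min), swelling included."""
        return 1000.0 * self.net_displacement / float(self.t[-1] - self.t[0])

    def to_frame(self, cell_id: str = "cell") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": cell_id,
                "frame": np.arange(len(self.t)),
                "t_min": self.t,
                "L_um": self.L,
                "tip_ng_um": self.tip_ng,
                "tip_g_um": self.tip_g,
                "x_um": self.x,
                "g_um": self.g,
                "drift_um_min": self.drift_applied,
            }
        )


TRUTH_COLUMNS = [
    "cell_id", "frame", "t_min", "L_um", "tip_ng_um", "tip_g_um",
    "x_um", "g_um", "drift_um_min",
]


def minm_drift(g, vmax: float, lam: float):
    """Tip-directed drift law v(g) = vmax * exp(-g / lam) (µm/min).

    Non-increasing in g; bounded by vmax. ``lam=inf`` gives the
    distance-independent law v(g) = vmax.
    """
    if not math.isfinite(lam):
        return vmax * np.ones_like(np.asarray(g, dtype=float))
    return vmax * np.exp(-np.asarray(g, dtype=float) / lam)


def simulate_trajectory(config: SimulationConfig) -> GroundTruthTrajectory:
    """Integrate the nuclear-motion SDE with the Euler-Maruyama scheme.

    x <- x + drift(x, t) dt + sigma sqrt(dt) xi,  xi ~ N(0, 1),
    with the drift set by ``config.mode`` and the position clamped to the
    cell interior with a margin of ``config.margin``. Deterministic given
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    t = np.arange(n) * cfg.dt
    tip_ng = -cfg.swell_rate * t
    tip_g = cfg.L0 + cfg.vg * t
    x = np.empty(n)
    drift_applied = np.zeros(n)
    x[0] = cfg.x0

    # myo52_mbc switch state: 0 = normal drift, multiplier in {0, -1} otherwise
    state_on = True
    aberrant_mult = 0.0
    p_on_off = 1.0 - math.exp(-cfg.reversal_rates[0] * cfg.dt)
    p_off_on = 1.0 - math.exp(-cfg.reversal_rates[1] * cfg.dt)

    for i in range(n - 1):
        g = tip_g[i] - x[i]
        if cfg.mode is Mode.WT_DMSO:
            mid = 0.5 * (tip_ng[i] + tip_g[i])
            drift = -cfg.k * (x[i] - mid)
        elif cfg.mode is Mode.WT_MBC:
            drift = float(minm_drift(g, cfg.vmax, cfg.lam))
        elif cfg.mode is Mode.CABLE_NULL_MBC:
            drift = 0.0
        else:  # MYO52_MBC
            base = float(minm_drift(g, cfg.vmax, cfg.lam))
            drift = base if state_on else aberrant_mult * base
            # advance the two-state Markov switch for the next step
            if state_on:
                if rng.random() < p_on_off:
                    state_on = False
                    aberrant_mult = float(rng.choice([0.0, -1.0]))
            elif rng.random() < p_off_on:
                state_on = True
        drift_applied[i] = drift
        step = drift * cfg.dt + cfg.sigma * math.sqrt(cfg.dt) * rng.standard_normal()
        xi = x[i] + step
        lo = tip_ng[i + 1] + cfg.margin
        hi = tip_g[i + 1] - cfg.margin
        x[i + 1] = min(max(xi, lo), hi)

    return GroundTruthTrajectory(
        config=cfg, t=t, L=tip_g - tip_ng, tip_ng=tip_ng, tip_g=tip_g,
        x=x, drift_applied=drift_applied,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Parameters of the 2D fluorescence renderer.

    The cell is drawn as a capped rod (stadium) with its long axis vertical,
    growing downward, a bright cap of length ``cap_length`` at the growing
    tip, and an anti-aliased bright disk of radius ``nucleus_radius`` at the
    nuclear position; optionally a medial septum band. Frames are blurred
    with a Gaussian PSF, corrupted with Poisson shot noise and Gaussian read
    noise, and quantized to 16 bits.
    """

    pixel_size: float = 0.10  # µm/px
    frame_dims: tuple[int, int] = (512, 128)  # (rows, cols) px
    cell_width: float = 3.5  # µm
    psf_sigma: float = 1.5  # px
    nucleus_radius: float = 1.2  # µm
    cap_length: float = 1.5  # µm
    background: float = 100.0
    cytoplasm: float = 400.0
    nucleus: float = 1500.0
    tip_cap: float = 2000.0
    septum: float = 2200.0
    read_noise_sd: float = 5.0  # counts; 0 disables
    photon_scaling: float = 1.0  # counts/photon; 0 disables shot noise
    bit_depth: int = 16
    draw_septum: bool = False
    septum_frac: float = 0.5  # axial position of the septum, fraction of length
    septum_width: float = 0.3  # µm
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nucleus_radius >= self.cell_width / 2:
            raise ValueError("nucleus_radius must be smaller than cell_width/2")


def _soft_disk(dist: np.ndarray) -> np.ndarray:
    """Anti-aliased indicator: 1 inside, 0 outside, linear ramp over 1 px."""
    return np.clip(0.5 - dist, 0.0, 1.0)


def _render_frame(tip_ng_um, tip_g_um, x_um, params: RenderParams,
                  row_of, col_center: float, septum_row: float | None) -> np.ndarray:
    """Noise-free frame (float counts) for one time point.

    ``row_of`` maps axial µm -> fractional row; the growing tip is at larger
    row (cell grows downward).
    """
    p = params
    H, W = p.frame_dims
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    half_w = 0.5 * p.cell_width / p.pixel_size

    r_ng = row_of(tip_ng_um)
    r_g = row_of(tip_g_um)
    if r_ng < -0.5 or r_g > H - 0.5:
        raise ValueError("cell exceeds frame bounds")
    # axis segment of the stadium: endpoints half_w inside each tip
    a = r_ng + half_w
    b = r_g - half_w
    dr = np.clip(rows, a, b)
    dist = np.hypot(rows - dr, cols - col_center) - half_w  # signed px distance
    cell_cov = _soft_disk(dist)

    img = p.background + (p.cytoplasm - p.background) * cell_cov

    # growing-tip cap: cell pixels within cap_length of the growing tip
    cap_px = p.cap_length / p.pixel_size
    cap_cov = cell_cov * np.clip(cap_px - (r_g - rows), 0.0, 1.0) * (rows > r_g - cap_px - 1)
    img += (p.tip_cap - p.cytoplasm) * np.clip(cap_cov, 0.0, 1.0)

    # nucleus disk
    r_nuc = row_of(x_um)
    nuc_r_px = p.nucleus_radius / p.pixel_size
    nd = np.hypot(rows - r_nuc, cols - col_center) - nuc_r_px
    img += (p.nucleus - p.cytoplasm) * _soft_disk(nd) * cell_cov

    if septum_row is not None:
        half_s = 0.5 * p.septum_width / p.pixel_size
        band = np.clip(half_s + 0.5 - np.abs(rows - septum_row), 0.0, 1.0)
        img += (p.septum - p.cytoplasm) * band * cell_cov

    return img


def render_stack(traj: GroundTruthTrajectory, params: RenderParams | None = None):
    """Render a trajectory as a calibrated 16-bit time-lapse stack.

    Returns a :class:`nucleodrift.stack.TimeLapseStack`. Deterministic given
    ``params.seed``.
    """
    from .stack import TimeLapseStack  # local import to avoid a cycle

    p = params or RenderParams()
    H, W = p.frame_dims
    rng = np.random.default_rng(p.seed)

    # anchor: center the full axial span of the movie in the frame
    span_lo = float(traj.tip_ng.min())
    span_hi = float(traj.tip_g.max())
    span_px = (span_hi - span_lo) / p.pixel_size
    if span_px > H - 4 or p.cell_width / p.pixel_size > W - 4:
        raise ValueError("cell exceeds frame bounds")
    row0 = 0.5 * (H - 1) - 0.5 * span_px - span_lo / p.pixel_size
    row_of = lambda um: row0 + um / p.pixel_size
    col_center = 0.5 * (W - 1)

    frames = np.empty((len(traj.t), H, W), dtype=np.uint16)
    qmax = 2 ** p.bit_depth - 1
    for i in range(len(traj.t)):
        septum_row = None
        if p.draw_septum:
            septum_row = row_of(traj.tip_ng[i]
                                + p.septum_frac * (traj.tip_g[i] - traj.tip_ng[i]))
        img = _render_frame(traj.tip_ng[i], traj.tip_g[i], traj.x[i], p,
                            row_of, col_center, septum_row)
        img = ndimage.gaussian_filter(img, p.psf_sigma)
        if p.photon_scaling > 0:
            img = rng.poisson(img / p.photon_scaling) * p.photon_scaling
        if p.read_noise_sd > 0:
            img = img + rng.normal(0.0, p.read_noise_sd, img.shape)
        frames[i] = np.clip(np.rint(img), 0, qmax).astype(np.uint16)

    return TimeLapseStack(
        frames=frames,
        pixel_size=p.pixel_size,
        frame_interval=traj.config.dt,
        provenance="synthetic",
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _draw_initial_conditions(rng, L0_range, x0_offset_sd, x0_um=None):
    L0 = float(rng.uniform(*L0_range))
    if x0_um is not None:
        x0 = float(x0_um if x0_um >= 0 else L0 + x0_um)  # negative = from growing tip
    else:
        x0 = L0 / 2 + float(np.clip(rng.normal(0.0, x0_offset_sd), -1.0, 1.0))
    return L0, x0


def generate_cohort(
    mode,
    n: int,
    seed: int,
    out_dir=None,
    L0_range: tuple[float, float] = (8.0, 11.0),
    x0_offset_sd: float = 0.5,
    x0_um: float | None = None,
    render: bool = True,
    config_overrides: dict | None = None,
    render_overrides: dict | None = None,
):
    """Simulate ``n`` independent cells with per-cell seeds spawned from ``seed``.

    Initial cell length is drawn uniformly from ``L0_range``; the initial
    nuclear position is the cell midpoint plus a clipped Gaussian offset
    (sd ``x0_offset_sd`` µm, clipped to ±1 µm), unless ``x0_um`` pins it
    (negative values count from the growing tip, e.g. ``x0_um=-2`` starts
    the nucleus 2 µm from the growing tip, a displaced-start cohort).

    Returns ``(cells, truth)`` where ``cells`` is a list of
    ``(cell_id, trajectory, stack_or_None)`` and ``truth`` the combined
    per-frame ground-truth table. If ``out_dir`` is given, writes one
    multi-page TIFF per cell, ``truth.csv``, and ``cohort.yaml``.
    """
    if n < 1:
        raise ValueError("cohort size n must be >= 1")
    mode = Mode(mode)
    master = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(master.spawn(1)[0])
    cell_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(n + 1)[1:]]

    cells = []
    truth_frames = []
    for i in range(n):
        L0, x0 = _draw_initial_conditions(init_rng, L0_range, x0_offset_sd, x0_um)
        kwargs = dict(mode=mode, L0=L0, x0=x0, seed=cell_seeds[i])
        if config_overrides:
            kwargs.update(config_overrides)
        cfg = SimulationConfig(**kwargs)
        traj = simulate_trajectory(cfg)
        cell_id = f"{mode.value}_{i:04d}"
        stack = None
        if render:
            rkwargs = dict(seed=cell_seeds[i])
            if render_overrides:
                rkwargs.update(render_overrides)
            stack = render_stack(traj, RenderParams(**rkwargs))
        cells.append((cell_id, traj, stack))
        truth_frames.append(traj.to_frame(cell_id))
    truth = pd.concat(truth_frames, ignore_index=True)

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cell_id, _traj, stack in cells:
            if stack is not None:
                tifffile.imwrite(out / f"{cell_id}.tif", stack.frames)
        truth.to_csv(out / "truth.csv", index=False)
        manifest = {
            "mode": mode.value,
            "n": n,
            "seed": int(seed),
            "L0_range": list(L0_range),
            "x0_offset_sd": x0_offset_sd,
            "x0_um": x0_um,
            "config_overrides": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in (config_overrides or {}).items()},
            "render_overrides": dict(render_overrides or {}),
            "cells": [cid for cid, _, _ in cells],
        }
        with open(out / "cohort.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    return cells, truth
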