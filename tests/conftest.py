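import numpy as np
import pytest

import nucleodrift as nd

# compact rendering geometry used throughout the unit tests: same optics as
# the defaults, smaller canvas for speed
SMALL_FRAME = dict(frame_dims=(256, 96))


@pytest.fixture(scope="session")
def quiet_render():
    """Render parameters with all noise sources disabled."""
    return nd.RenderParams(photon_scaling=0.0, read_noise_sd=0.0, **SMALL_FRAME)


@pytest.fixture(scope="session")
def noisy_render():
    """Default noise model on the compact canvas."""
    return nd.RenderParams(**SMALL_FRAME)


@pytest.fixture(scope="session")
def mbc_cell(quiet_render):
    """One noise-free MBC-regime cell: (trajectory, stack)."""
    cfg = nd.SimulationConfig(mode="wt_mbc", L0=9.5, x0=4.75, sigma=0.0, seed=5)
    traj = nd.simulate_trajectory(cfg)
    return traj, nd.render_stack(traj, quiet_render)


@pytest.fixture(scope="session")
def mbc_cell_analyzed(mbc_cell):
    traj, stack = mbc_cell
    return traj, nd.analyze_stack(stack, cell_id="mbc0")


def render_single_frame(x_um, L0=9.5, params=None, **cfg_kwargs):
    """Stack with one noise-free frame, nucleus at ``x_um``."""
    params = params or nd.RenderParams(photon_scaling=0.0, read_noise_sd=0.0,
                                       **SMALL_FRAME)
    cfg = nd.SimulationConfig(mode="cable_null_mbc", L0=L0, x0=x_um, sigma=0.0,
                              swell_rate=0.0, duration=cfg_kwargs.pop("duration", 0.0) or 5.0,
                              dt=5.0, seed=0, **cfg_kwargs)
    traj = nd.simulate_trajectory(cfg)
    return traj, nd.render_stack(traj, params)
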