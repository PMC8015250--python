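"""Trajectory model: determinism, drift laws, confinement, stationarity."""

import numpy as np
import pytest

import nucleodrift as nd
from nucleodrift.simulate import Mode, minm_drift


def ou_reference(x0, target, k, t_end, dt=0.001):
    """Independent fine-step integrator for dx/dt = -k (x - target)."""
    x = x0
    for _ in range(int(round(t_end / dt))):
        x += -k * (x - target) * dt
    return x


class TestSimulateTrajectory:
    def test_no_force_no_noise_is_constant(self):
        cfg = nd.SimulationConfig(mode="cable_null_mbc", sigma=0.0,
                                  swell_rate=0.0, seed=1)
        traj = nd.simulate_trajectory(cfg)
        assert np.allclose(traj.x, cfg.x0)
        assert traj.net_displacement == pytest.approx(0.0)

    def test_centering_relaxation_matches_reference_integrator(self):
        # deterministic restoring force toward the midpoint of a static cell
        cfg = nd.SimulationConfig(mode="wt_dmso", L0=10.0, x0=7.0, vg=0.0,
                                  k=0.1, sigma=0.0, swell_rate=0.0,
                                  vmax=0.0, duration=10.0, dt=0.01, seed=0)
        traj = nd.simulate_trajectory(cfg)
        expected = ou_reference(7.0, 5.0, 0.1, 10.0)
        assert traj.x[-1] == pytest.approx(expected, abs=1e-3)

    def test_mbc_ensemble_mean_matches_deterministic_drift(self):
        # with the noise switched off the trajectory is the deterministic
        # integral of v(g(t)); the noisy ensemble mean must agree with it
        det = nd.simulate_trajectory(
            nd.SimulationConfig(mode="wt_mbc", sigma=0.0, seed=0))
        disps = []
        for seed in range(500):
            traj = nd.simulate_trajectory(
                nd.SimulationConfig(mode="wt_mbc", sigma=0.03, seed=seed))
            disps.append(traj.net_displacement)
        disps = np.asarray(disps)
        ci99 = 2.576 * disps.std(ddof=1) / np.sqrt(len(disps))
        assert abs(disps.mean() - det.net_displacement) < ci99 + 1e-9

    def test_same_seed_reproduces_trajectory(self):
        cfg = nd.SimulationConfig(mode="myo52_mbc", seed=42)
        a = nd.simulate_trajectory(cfg)
        b = nd.simulate_trajectory(cfg)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.drift_applied, b.drift_applied)

    @pytest.mark.parametrize("mode", [m.value for m in Mode])
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_nucleus_confined_to_cell(self, mode, seed):
        cfg = nd.SimulationConfig(mode=mode, sigma=0.08, seed=seed)
        traj = nd.simulate_trajectory(cfg)
        assert np.all(traj.x - traj.tip_ng >= cfg.margin - 1e-9)
        assert np.all(traj.tip_g - traj.x >= cfg.margin - 1e-9)
        assert np.all(np.diff(traj.tip_g) > 0)  # vg > 0: tip strictly advances
        assert np.allclose(traj.g, traj.tip_g - traj.x)

    def test_drift_law_monotone_and_capped(self):
        g = np.linspace(0.0, 12.0, 200)
        v = minm_drift(g, vmax=0.03, lam=6.0)
        assert np.all(np.diff(v) <= 0)
        assert np.all(v <= 0.03 + 1e-12)
        assert np.allclose(minm_drift(g, 0.012, np.inf), 0.012)

    def test_dmso_stationary_variance(self):
        # Ornstein-Uhlenbeck in a static cell: var(x) -> sigma^2 / (2k)
        cfg = nd.SimulationConfig(mode="wt_dmso", L0=10.0, x0=5.0, vg=0.0,
                                  vmax=0.0, k=0.1, sigma=0.05, swell_rate=0.0,
                                  duration=2000.0, dt=0.5, seed=11)
        traj = nd.simulate_trajectory(cfg)
        x = traj.x[400:]  # discard burn-in
        expected = cfg.sigma ** 2 / (2 * cfg.k)
        assert np.var(x) == pytest.approx(expected, rel=0.25)

    def test_myo52_switching_produces_stalls_and_reversals(self):
        drifts = np.concatenate([
            nd.simulate_trajectory(
                nd.SimulationConfig(mode="myo52_mbc", duration=300.0, seed=s)
            ).drift_applied[:-1]
            for s in range(5)
        ])
        assert (drifts > 0).any()
        assert (drifts <= 0).any()  # aberrant state: stalled or reversed

    @pytest.mark.parametrize("kwargs", [
        dict(x0=-1.0), dict(x0=12.0), dict(dt=0.0), dict(dt=-5.0),
        dict(vmax=0.05), dict(duration=7.0),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nd.SimulationConfig(mode="wt_mbc", **kwargs)


class TestGenerateCohort:
    def test_master_seed_determinism(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        nd.generate_cohort("wt_mbc", 3, seed=7, out_dir=a,
                           render_overrides=dict(frame_dims=(256, 96)))
        nd.generate_cohort("wt_mbc", 3, seed=7, out_dir=b,
                           render_overrides=dict(frame_dims=(256, 96)))
        for name in ["truth.csv", "wt_mbc_0000.tif"]:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_mbc_cohort_truth_table(self):
        cells, truth = nd.generate_cohort("wt_mbc", 10, seed=3, render=False)
        assert truth["cell_id"].nunique() == 10
        assert (truth["drift_um_min"] >= 0).all()
        # one row per cell and frame
        assert len(truth) == 10 * cells[0][1].config.n_frames

    def test_displaced_start_has_stronger_initial_drift(self):
        near, _ = nd.generate_cohort("wt_mbc", 5, seed=9, x0_um=-1.0,
                                     render=False)
        far, _ = nd.generate_cohort("wt_mbc", 5, seed=9, x0_um=-6.0,
                                    render=False)
        v_near = np.mean([t.drift_applied[0] for _, t, _ in near])
        v_far = np.mean([t.drift_applied[0] for _, t, _ in far])
        assert v_near > v_far  # v(g) decreases with distance from the tip

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            nd.generate_cohort("wt_mbc", 0, seed=1)
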