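"""Movement statistics: velocities, ratios, septum, regression."""

import numpy as np
import pytest

import nucleodrift as nd
from nucleodrift.metrics import Direction, classify_direction
from conftest import SMALL_FRAME


def synthetic_track_and_geometry(d_ng, tip_g, frame_interval=5.0,
                                 growing="tip_B"):
    """Hand-built track/geometry pair with prescribed distances (µm)."""
    from nucleodrift.geometry import CellGeometry, GrowingTip, GrowthMode
    from nucleodrift.tracking import NuclearTrack, QCFlag
    d_ng = np.asarray(d_ng, dtype=float)
    tip_g = np.asarray(tip_g, dtype=float)
    n = len(d_ng)
    geom = CellGeometry(
        masks=np.ones((n, 4, 4), bool), axis_angle=90.0,
        tip_a_um=np.zeros(n), tip_b_um=tip_g,
        growing_tip=GrowingTip(growing), growth_mode=GrowthMode.MONOPOLAR,
        pixel_size=0.1, frame_interval=frame_interval,
        origin_row=0.0, axis_sign=1, axis_col=2.0)
    x = d_ng  # tip_ng pinned at 0
    track = NuclearTrack(
        t_min=np.arange(n) * frame_interval,
        centroid_px=np.zeros((n, 2)), x_um=x, d_ng_um=d_ng,
        d_g_um=tip_g - x, qc_flag=[QCFlag.OK] * n)
    return track, geom


class TestNetVelocity:
    def test_static_everything_is_zero(self):
        track, geom = synthetic_track_and_geometry(
            d_ng=[5.0] * 10, tip_g=[10.0] * 10)
        s = nd.net_velocity(track, geom)
        assert s.net_velocity_nm_min == pytest.approx(0.0)
        assert s.direction is Direction.STATIONARY

    def test_constant_advance_measures_12_nm_min(self):
        # the canonical tip-directed velocity: 12 nm/min over a 90-min movie
        t = np.arange(19) * 5.0
        track, geom = synthetic_track_and_geometry(
            d_ng=5.0 + 0.012 * t, tip_g=10.0 + 0.03 * t)
        s = nd.net_velocity(track, geom)
        assert s.net_velocity_nm_min == pytest.approx(12.0)
        assert s.direction is Direction.TOWARD
        assert s.normalized_velocity == pytest.approx(12.0 / 30.0, rel=1e-6)

    def test_swelling_artifact_reported_uncorrected(self):
        # a stationary nucleus plus 2 nm/min tip swelling appears to move at
        # 2 nm/min: reproduced end-to-end from a rendered movie
        cfg = nd.SimulationConfig(mode="cable_null_mbc", sigma=0.0,
                                  swell_rate=0.002, seed=4)
        traj = nd.simulate_trajectory(cfg)
        stack = nd.render_stack(traj, nd.RenderParams(
            photon_scaling=0.0, read_noise_sd=0.0, **SMALL_FRAME))
        res = nd.analyze_stack(stack)
        assert traj.net_velocity_nm_min == pytest.approx(2.0, abs=1e-9)
        assert res.summary.net_velocity_nm_min == pytest.approx(2.0, abs=0.5)

    def test_requires_monopolar(self):
        track, geom = synthetic_track_and_geometry([5.0] * 4, [10.0] * 4)
        from nucleodrift.geometry import GrowthMode
        geom.growth_mode = GrowthMode.BIPOLAR
        with pytest.raises(ValueError, match="monopolar"):
            nd.net_velocity(track, geom)


class TestClassifyDirection:
    @pytest.mark.parametrize("disp,expected", [
        (1.0, Direction.TOWARD), (0.0, Direction.STATIONARY),
        (0.25, Direction.STATIONARY), (-0.6, Direction.AWAY),
    ])
    def test_thresholding(self, disp, expected):
        assert classify_direction(disp, epsilon=0.25) is expected

    def test_pipeline_fraction_matches_truth_level_prediction(self):
        # truth-level Monte Carlo prediction of the "toward" fraction
        cells, _ = nd.generate_cohort("wt_mbc", 200, seed=21, render=False)
        disps = np.array([t.net_displacement for _, t, _ in cells])
        frac = np.mean(disps > 0.25)
        assert frac > 0.95  # tip-directed drift dominates the diffusion


class TestRatios:
    def test_centered_nucleus(self):
        m = nd.centering_ratio(5.0, 0.0, 10.0)
        assert m.ratio_sl == pytest.approx(1.0)
        assert m.ratio_s_total == pytest.approx(0.5)

    def test_off_center_arithmetic(self):
        m = nd.centering_ratio(3.0, 0.0, 12.0)
        assert m.ratio_sl == pytest.approx(1 / 3)
        assert m.ratio_s_total == pytest.approx(0.25)

    def test_bounds(self):
        for x in np.linspace(0.3, 11.7, 23):
            m = nd.centering_ratio(x, 0.0, 12.0)
            assert 0 < m.ratio_sl <= 1
            assert 0 < m.ratio_s_total <= 0.5

    def test_nucleus_at_tip_rejected(self):
        with pytest.raises(ValueError):
            nd.centering_ratio(0.0, 0.0, 10.0)

    def test_rendered_ratio_tracks_truth(self, mbc_cell_analyzed):
        traj, res = mbc_cell_analyzed
        g = res.geometry
        m = nd.centering_ratio(res.track.x_um[0], g.tip_a_um[0], g.tip_b_um[0])
        s_t, l_t = sorted([traj.d_ng[0], traj.g[0]])
        assert m.ratio_sl == pytest.approx(s_t / l_t, abs=0.02)

    def test_ab_arithmetic_and_antisymmetry(self):
        m = nd.ab_ratio(2.0, 0.0, 10.0)
        assert m.ratio_ab == pytest.approx(0.25)
        assert m.log2_ratio == pytest.approx(-2.0)
        swapped = nd.ab_ratio(2.0, 10.0, 0.0)
        assert swapped.log2_ratio == pytest.approx(-m.log2_ratio)

    def test_centered_ab_is_unity(self):
        m = nd.ab_ratio(5.0, 0.0, 10.0)
        assert m.ratio_ab == pytest.approx(1.0)
        assert m.log2_ratio == pytest.approx(0.0)


class TestSeptumPosition:
    @staticmethod
    def _septating_frame(frac):
        cfg = nd.SimulationConfig(mode="cable_null_mbc", L0=11.0, x0=2.6,
                                  sigma=0.0, swell_rate=0.0, seed=0)
        traj = nd.simulate_trajectory(cfg)
        params = nd.RenderParams(photon_scaling=0.0, read_noise_sd=0.0,
                                 draw_septum=True, septum_frac=frac,
                                 **SMALL_FRAME)
        stack = nd.render_stack(traj, params)
        geom = nd.analyze_geometry(
            nd.TimeLapseStack(stack.frames.astype(float), stack.pixel_size,
                              stack.frame_interval))
        return stack.frames[0], geom

    @pytest.mark.parametrize("frac,expected", [(0.5, 0.5), (0.4, 0.4)])
    def test_rendered_septum_located(self, frac, expected):
        frame, geom = self._septating_frame(frac)
        m = nd.septum_position(frame, geom, nucleus_x_um=2.6)
        assert m.ratio_s_total == pytest.approx(expected, abs=0.01)

    def test_interphase_frame_has_no_septum(self, mbc_cell_analyzed):
        traj, res = mbc_cell_analyzed
        with pytest.raises(LookupError, match="no septum"):
            nd.septum_position(res.rotated.frames[0], res.geometry,
                               nucleus_x_um=traj.x[0])


class TestRegression:
    def test_collinear_points(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        r = nd.velocity_position_regression(x, 10 + 30 * x)
        assert r.r2 == pytest.approx(1.0)
        assert r.slope == pytest.approx(30.0)

    def test_flat_response(self):
        r = nd.velocity_position_regression([0.1, 0.2, 0.3], [5.0, 5.0, 5.0])
        assert r.slope == 0.0 and r.r2 == 0.0 and r.p_value == 1.0

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            nd.velocity_position_regression([0.2, 0.2, 0.2], [1.0, 2.0, 3.0])

    def test_needs_three_cells(self):
        with pytest.raises(ValueError):
            nd.velocity_position_regression([0.1, 0.2], [1.0, 2.0])


class TestGrowthRate:
    def test_recovers_truth_noise_free(self):
        cfg = nd.SimulationConfig(mode="wt_mbc", sigma=0.0, swell_rate=0.0,
                                  seed=5)
        traj = nd.simulate_trajectory(cfg)
        stack = nd.render_stack(traj, nd.RenderParams(
            photon_scaling=0.0, read_noise_sd=0.0, **SMALL_FRAME))
        res = nd.analyze_stack(stack)
        assert nd.growth_rate(res.geometry) == pytest.approx(30.0, abs=0.5)

    def test_swelling_adds_apparent_growth(self, mbc_cell_analyzed):
        # with the static pole swelling at 2 nm/min, apparent tip growth in
        # the anchored frame is vg + swell_rate
        _, res = mbc_cell_analyzed
        assert nd.growth_rate(res.geometry) == pytest.approx(32.0, abs=0.5)

    def test_static_tips_zero(self):
        track, geom = synthetic_track_and_geometry([5.0] * 6, [10.0] * 6)
        from nucleodrift.geometry import GrowthMode, GrowingTip
        geom.growth_mode = GrowthMode.NONE
        geom.growing_tip = GrowingTip.NONE
        assert nd.growth_rate(geom) == pytest.approx(0.0)

    def test_sampling_interval_invariance(self):
        t5 = np.arange(19) * 5.0
        track5, geom5 = synthetic_track_and_geometry(
            5 + 0.012 * t5, 10 + 0.03 * t5, frame_interval=5.0)
        t10 = np.arange(10) * 10.0
        track10, geom10 = synthetic_track_and_geometry(
            5 + 0.012 * t10, 10 + 0.03 * t10, frame_interval=10.0)
        assert nd.growth_rate(geom5) == pytest.approx(nd.growth_rate(geom10),
                                                      abs=0.5)
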