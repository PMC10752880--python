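import numpy as np
import pytest

from phasetrack import (Settings, SyntheticSpec, build_tracks,
                        compute_track_metrics, count_cells_over_time,
                        generate_video, process_video, velocity_distribution,
                        wound_signed_fmi)
from phasetrack.metrics import (assign_wound_sides, mean_velocity_over_time,
                                two_stage_mean_velocity)
from phasetrack.tracking import Track
from helpers import observations, trajectory


def _track(points, tid=0):
    return trajectory(points, tid)


class TestTrackMetrics:
    def test_straight_track(self):
        m = compute_track_metrics(
            _track([(0, 0), (5, 0), (10, 0), (15, 0), (20, 0)]), dt=10.0)
        assert m.mean_step_velocity == pytest.approx(0.5)
        assert m.directness == pytest.approx(1.0)
        assert m.euclidean_distance == pytest.approx(20.0)
        assert m.duration == 40.0

    def test_right_angle_track(self):
        m = compute_track_metrics(_track([(0, 0), (10, 0), (10, 10)]), dt=10.0)
        assert m.accumulated_distance == pytest.approx(20.0, abs=0)
        assert m.euclidean_distance == pytest.approx(np.sqrt(200.0), abs=0)
        assert m.directness == pytest.approx(np.sqrt(0.5), abs=1e-15)

    def test_straight_down_fmi(self):
        m = compute_track_metrics(_track([(0, 0), (0, 5), (0, 10)]), dt=10.0)
        assert m.fmi_y == pytest.approx(1.0)
        assert m.fmi_x == pytest.approx(0.0)

    def test_static_track_has_nan_markers(self):
        m = compute_track_metrics(_track([(3, 3), (3, 3), (3, 3)]), dt=10.0)
        assert np.isnan(m.directness) and np.isnan(m.fmi_x)
        assert m.mean_step_velocity == 0.0

    def test_directness_identity_on_random_tracks(self, rng):
        # directness == euclidean_velocity / mean_step_velocity
        for _ in range(20):
            pts = rng.uniform(0, 100, (rng.integers(3, 30), 2))
            m = compute_track_metrics(trajectory(pts), dt=7.0)
            assert m.directness == pytest.approx(
                m.euclidean_velocity / m.mean_step_velocity, abs=1e-12)
            assert 0.0 <= m.directness <= 1.0
            assert m.euclidean_distance <= m.accumulated_distance + 1e-12
            assert abs(m.fmi_x) <= 1.0 and abs(m.fmi_y) <= 1.0


class TestWoundFmi:
    def test_top_side_moving_down_positive(self):
        m = compute_track_metrics(_track([(0, 0), (0, 10)]), dt=10.0)
        assert wound_signed_fmi(m, "top").fmi_y > 0

    def test_bottom_side_moving_up_positive_after_flip(self):
        m = compute_track_metrics(_track([(0, 100), (0, 90)]), dt=10.0)
        assert m.fmi_y < 0
        assert wound_signed_fmi(m, "bottom").fmi_y > 0

    def test_symmetric_wound_signed_positive_unsigned_near_zero(self):
        spec = SyntheticSpec(frame_shape=(300, 300), pixel_size=1.0,
                             n_frames=12, n_cells=14, cell_diameter=13.0,
                             sigma_step=0.3, noise_sd=0.0,
                             wound_band=(120.0, 180.0), wound_drift=1.5,
                             min_separation_factor=2.0, seed=9)
        _, truth = generate_video(spec)
        settings = Settings(pixel_size=1.0, highest_cell_velocity=1.0,
                            shortest_cell_track=5)
        frames = [observations(truth.positions_at(t).values())
                  for t in range(spec.n_frames)]
        ts = build_tracks(frames, settings)
        sides = assign_wound_sides(ts.tracks)
        raw = [compute_track_metrics(t, 10.0) for t in ts]
        signed = [wound_signed_fmi(m, sides[m.track_id]) for m in raw]
        assert np.mean([m.fmi_y for m in signed]) > 0.3
        assert abs(np.mean([m.fmi_y for m in raw])) < 0.15


class TestMeanVelocityOverTime:
    def test_static_cells_zero(self):
        tracks = [_track([(10, 10)] * 5), _track([(40, 40)] * 5, tid=1)]
        out = mean_velocity_over_time(tracks, dt=10.0, n_frames=5)
        assert all(s.mean_step_velocity == 0.0 for s in out)

    def test_uniform_drift_recovered_every_step(self):
        tracks = [_track([(i * 3.0, 0.0) for i in range(6)]),
                  _track([(50 + i * 3.0, 20.0) for i in range(6)], tid=1)]
        out = mean_velocity_over_time(tracks, dt=10.0, n_frames=6)
        assert all(s.mean_step_velocity == pytest.approx(0.3) for s in out)

    def test_two_stage_mean_matches_direct_computation(self, rng):
        tracks = [trajectory(rng.uniform(0, 50, (8, 2)), tid=i)
                  for i in range(4)]
        out = mean_velocity_over_time(tracks, dt=5.0, n_frames=8)
        direct = np.mean([
            np.mean([np.linalg.norm(np.diff(t.positions, axis=0), axis=1)[k]
                     for t in tracks]) / 5.0
            for k in range(7)])
        assert two_stage_mean_velocity(out) == pytest.approx(direct, rel=1e-12)

    def test_empty_step_yields_nan(self):
        tracks = [Track(0, observations([(0, 0), (1, 0)]))]
        out = mean_velocity_over_time(tracks, dt=10.0, n_frames=4)
        assert np.isnan(out[2].mean_step_velocity)


class TestVelocityDistribution:
    def test_symmetric_counts_vertex_at_centre(self):
        # counts {4,9,12,9,4} in bins centred 0.5..4.5: symmetric about 2.5
        values = np.repeat([0.5, 1.5, 2.5, 3.5, 4.5], [4, 9, 12, 9, 4])
        d = velocity_distribution(values, 1.0)
        assert d.mode == pytest.approx(2.5)
        assert d.normalized.sum() == pytest.approx(100.0, abs=1e-9)

    def test_vertex_matches_independent_quadratic_fit(self):
        counts = [2, 6, 12, 10, 3]
        values = np.repeat([0.5, 1.5, 2.5, 3.5, 4.5], counts)
        d = velocity_distribution(values, 1.0)
        # independent least-squares oracle via the normal equations
        x = np.array([0.5, 1.5, 2.5, 3.5, 4.5])
        A = np.column_stack([x ** 2, x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, np.array(counts, float), rcond=None)
        expected = -coef[1] / (2 * coef[0])
        assert d.mode == pytest.approx(expected, abs=1e-9)

    def test_degenerate_single_bin_warns(self):
        with pytest.warns(UserWarning, match="peak"):
            d = velocity_distribution(np.full(50, 3.2), 1.0)
        assert d.mode == pytest.approx(3.5)      # centre of bin [3, 4)

    def test_accumulated_monotone_to_100(self, rng):
        d = velocity_distribution(rng.exponential(2.0, 500), 0.5)
        assert np.all(np.diff(d.accumulated) >= -1e-12)
        assert d.accumulated[-1] == pytest.approx(100.0, abs=1e-9)

    def test_median_interpolated(self, rng):
        vals = rng.uniform(0, 10, 10001)
        d = velocity_distribution(vals, 1.0)
        assert d.median == pytest.approx(np.median(vals), abs=0.2)


class TestCellCounts:
    def test_static_video_constant_count(self, unit_settings):
        spec = SyntheticSpec(frame_shape=(250, 250), pixel_size=1.0,
                             n_frames=5, n_cells=9, cell_diameter=14.0,
                             sigma_step=0.0, noise_sd=2.0,
                             min_separation_factor=2.5, seed=2)
        stack, _ = generate_video(spec)
        res = process_video(stack, unit_settings)
        counts = count_cells_over_time(res.frame_results)
        assert list(counts) == [9] * 5

    def test_division_growth_rate_recovered(self, unit_settings):
        # proliferation imaging: every 3 h for 72 h; per-step Brownian
        # motion is large at this interval, so daughters separate quickly
        spec = SyntheticSpec(frame_shape=(480, 480), pixel_size=1.0,
                             n_frames=24, dt=180.0, n_cells=18,
                             cell_diameter=13.0, cell_diameter_sd=0.5,
                             sigma_step=8.0, noise_sd=2.0,
                             division_prob=0.09,
                             min_separation_factor=2.2, seed=17)
        stack, truth = generate_video(spec)
        res = process_video(stack, unit_settings)
        measured = count_cells_over_time(res.frame_results).astype(float)
        alive = np.array([len(truth.positions_at(t))
                          for t in range(spec.n_frames)], dtype=float)
        t = np.arange(spec.n_frames)
        rate_measured = np.polyfit(t, np.log(measured), 1)[0]
        rate_true = np.polyfit(t, np.log(alive), 1)[0]
        assert rate_measured == pytest.approx(rate_true, rel=0.15)
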