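import numpy as np
from scipy import stats

from phasetrack import Settings, build_tracks, filter_valid_tracks, match_frames
from phasetrack.tracking import CellObservation, Track, TrackSet, smooth_track
from helpers import (brute_force_assignment, observations, trajectory,
                     walk_detections)


def _settings(max_step=20.0, shortest=4):
    # highest velocity * dt = max step
    return Settings(pixel_size=1.0, time_between_images=10.0,
                    highest_cell_velocity=max_step / 10.0,
                    shortest_cell_track=shortest)


class TestMatchFrames:
    def test_stationary_cells_identity(self):
        prev = observations([(0, 0), (50, 50)])
        now = observations([(0.5, 0), (50, 50.5)], 1)
        assert match_frames(now, prev, 5.0) == {0: 0, 1: 1}

    def test_least_moved_matched_first(self):
        # distances A-a 1, A-b 2, B-b 3: greedy takes A-a then B-b
        prev = observations([(0, 0), (0, 5)])     # A, B
        now = observations([(1, 0), (0, 2)], 1)   # a, b
        assert match_frames(now, prev, 4.0) == {0: 0, 1: 1}

    def test_beyond_max_step_unmatched(self):
        prev = observations([(0, 0)])
        now = observations([(10, 0)], 1)
        assert match_frames(now, prev, 5.0) == {}

    def test_greedy_against_exhaustive_assignment(self, rng):
        agree = 0
        trials = 50
        for _ in range(trials):
            prev = rng.uniform(0, 100, (5, 2))
            now = prev + rng.normal(0, 3.0, (5, 2))
            greedy = match_frames(observations(now, 1), observations(prev),
                                  max_step=1e9)
            if greedy == brute_force_assignment(prev, now):
                agree += 1
        assert agree / trials >= 0.95


class TestGapRepair:
    def test_midpoint_insertion(self):
        frames = [observations([(0.0, 0.0)]), [], observations([(2.0, 2.0)])]
        ts = build_tracks(frames, _settings(max_step=5.0))
        assert len(ts) == 1
        trk = ts.tracks[0]
        assert len(trk) == 3
        mid = trk.observations[1]
        assert (mid.x, mid.y) == (1.0, 1.0)
        assert mid.repaired and mid.frame_index == 1
        assert not trk.observations[0].repaired
        assert not trk.observations[2].repaired

    def test_no_repair_beyond_twice_max_step(self):
        frames = [observations([(0.0, 0.0)]), [],
                  observations([(12.5, 0.0)])]   # 2.5 x max_step away
        ts = build_tracks(frames, _settings(max_step=5.0))
        assert len(ts) == 2

    def test_dropout_fixture_repaired_at_deleted_frames(self, rng):
        n_frames = 30
        frames, truth = walk_detections(rng, 1, n_frames, sigma=1.0)
        deleted = [7, 14, 21, 28]
        for f in deleted:
            frames[f] = []
        ts = build_tracks(frames, _settings(max_step=20.0))
        assert len(ts) == 1
        trk = ts.tracks[0]
        assert len(trk) == n_frames
        repaired = [o.frame_index for o in trk.observations if o.repaired]
        assert repaired == deleted


class TestBuildTracks:
    def test_k_cells_give_k_full_tracks(self, rng):
        frames, _ = walk_detections(rng, 6, 15, sigma=1.5)
        ts = build_tracks(frames, _settings(max_step=20.0))
        assert len(ts) == 6
        assert all(len(t) == 15 for t in ts)

    def test_division_starts_one_new_track(self, rng):
        frames, _ = walk_detections(rng, 3, 10, sigma=0.5)
        # at frame 5 one cell becomes two detections 8 µm apart
        parent = frames[5][0]
        for f in range(5, 10):
            extra = CellObservation(f, parent.x + 8.0, parent.y, 0.0)
            frames[f] = frames[f] + [extra]
        ts = build_tracks(frames, _settings(max_step=20.0))
        assert len(ts) == 4           # K + 1

    def test_observation_conservation(self, rng):
        frames, _ = walk_detections(rng, 5, 12, sigma=2.0)
        frames[4] = frames[4][:3]     # a couple of missed detections
        frames[8] = frames[8][1:]
        ts = build_tracks(frames, _settings(max_step=25.0))
        n_detections = sum(len(f) for f in frames)
        n_repaired = sum(o.repaired for t in ts for o in t.observations)
        assert ts.n_observations() - n_repaired == n_detections

    def test_steps_never_exceed_max_step_except_repair_flanks(self, rng):
        frames, _ = walk_detections(rng, 8, 20, sigma=3.0)
        max_step = 15.0
        ts = build_tracks(frames, _settings(max_step=max_step))
        for trk in ts:
            obs = trk.observations
            for a, b in zip(obs, obs[1:]):
                step = np.hypot(b.x - a.x, b.y - a.y)
                if a.repaired or b.repaired:
                    assert step <= max_step + 1e-9
                else:
                    assert step <= max_step + 1e-9

    def test_linker_does_not_bias_step_distribution(self, rng):
        # Brownian ground truth fed as detections: measured step lengths
        # must match the generator's Rayleigh distribution (KS test)
        sigma = 2.0
        frames, _ = walk_detections(rng, 100, 21, sigma=sigma, extent=4000.0)
        ts = build_tracks(frames, _settings(max_step=20.0))
        steps = np.concatenate([
            np.linalg.norm(np.diff(t.positions, axis=0), axis=1) for t in ts])
        assert len(steps) == 2000
        p = stats.kstest(steps, "rayleigh", args=(0, sigma)).pvalue
        assert p > 0.01


class TestSmoothing:
    def _zigzag(self):
        return trajectory([(i, 5.0 if i % 2 else 0.0) for i in range(12)])

    def test_zero_iterations_identity(self):
        trk = self._zigzag()
        out = smooth_track(trk, 0)
        np.testing.assert_array_equal(out.positions, trk.positions)

    def test_collinear_track_is_fixed_point(self):
        trk = trajectory([(i * 3.0, i * 4.0) for i in range(8)])
        out = smooth_track(trk, 5)
        np.testing.assert_allclose(out.positions, trk.positions, atol=1e-12)

    def test_zigzag_accumulated_decreases_euclidean_fixed(self):
        trk = self._zigzag()

        def acc(t):
            return np.linalg.norm(np.diff(t.positions, axis=0), axis=1).sum()

        prev = trk
        for i in range(1, 4):
            cur = smooth_track(trk, i)
            assert acc(cur) < acc(prev) - 1e-9
            np.testing.assert_array_equal(cur.positions[0], trk.positions[0])
            np.testing.assert_array_equal(cur.positions[-1], trk.positions[-1])
            prev = cur

    def test_repaired_flags_preserved(self):
        trk = trajectory([(0, 0), (1, 1), (2, 0)])
        trk.observations[1] = CellObservation(1, 1.0, 1.0, 0.0, repaired=True)
        out = smooth_track(trk, 2)
        assert out.observations[1].repaired


class TestFilterValidTracks:
    def _track_set(self, lengths):
        tracks = [trajectory([(j, 0.0) for j in range(n)], tid=i)
                  for i, n in enumerate(lengths)]
        return TrackSet(tracks, dt=10.0)

    def test_short_track_excluded(self):
        ts = self._track_set([4, 5, 6])
        assert [t.id for t in filter_valid_tracks(ts, 5)] == [1, 2]

    def test_threshold_two_keeps_all_multi_observation(self):
        ts = self._track_set([1, 2, 3, 9])
        assert len(filter_valid_tracks(ts, 2)) == 3

    def test_raising_threshold_never_increases_count(self, rng):
        ts = self._track_set(list(rng.integers(1, 20, 30)))
        counts = [len(filter_valid_tracks(ts, k)) for k in range(2, 22)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
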