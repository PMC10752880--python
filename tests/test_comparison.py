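import numpy as np
import pandas as pd
import pytest

from phasetrack import (distance_distribution, gold_truth_mean,
                        match_track_sets, tracks_from_table,
                        velocity_agreement)
from helpers import trajectory


def _table(tracks):
    rows = [{"track_id": t.id, "frame": o.frame_index,
             "x_um": o.x, "y_um": o.y}
            for t in tracks for o in t.observations]
    return pd.DataFrame(rows)


def _random_tracks(rng, n, length=10, extent=500.0):
    starts = rng.uniform(50, extent - 50, (n, 2))
    out = []
    for i, s in enumerate(starts):
        pts = s + np.cumsum(rng.normal(0, 2.0, (length, 2)), axis=0)
        out.append(trajectory(pts, tid=i))
    return out


class TestMatchTrackSets:
    def test_identical_sets_fully_matched_at_zero(self, rng):
        tracks = _random_tracks(rng, 8)
        pairs = match_track_sets(tracks, tracks)
        assert len(pairs) == 8
        assert all(p.start_distance == 0 for p in pairs)
        assert all(np.all(p.distances == 0) for p in pairs)

    def test_sixteen_micron_start_not_matched(self):
        a = [trajectory([(0, 0), (1, 0)])]
        b = [trajectory([(16, 0), (17, 0)])]
        assert match_track_sets(a, b) == []
        assert len(match_track_sets(a, b, threshold=20.0)) == 1

    def test_partial_overlap_matches_known_correspondence(self, rng):
        tracks_a = _random_tracks(rng, 20)
        # method B re-detects a noisy subset with different ids
        tracks_b = []
        for k, t in enumerate(tracks_a[:14]):
            pts = t.positions + rng.normal(0, 1.0, t.positions.shape)
            tracks_b.append(trajectory(pts, tid=100 + k))
        pairs = match_track_sets(tracks_a, tracks_b)
        assert len(pairs) == 14
        assert all(p.id_b == p.id_a + 100 for p in pairs)

    def test_symmetric_under_swap(self, rng):
        a = _random_tracks(rng, 10)
        b = _random_tracks(rng, 12)
        ab = {(p.id_a, p.id_b) for p in match_track_sets(a, b)}
        ba = {(p.id_b, p.id_a) for p in match_track_sets(b, a)}
        assert ab == ba


class TestGoldTruth:
    def test_identical_annotators(self, rng):
        t = _table(_random_tracks(rng, 3))
        out = gold_truth_mean([t, t.copy(), t.copy()])
        pd.testing.assert_frame_equal(
            out.sort_values(["track_id", "frame"]).reset_index(drop=True),
            t.sort_values(["track_id", "frame"]).reset_index(drop=True),
            check_dtype=False)

    def test_two_annotators_average(self):
        a = pd.DataFrame([{"track_id": 0, "frame": 0, "x_um": 0.0, "y_um": 0.0}])
        b = pd.DataFrame([{"track_id": 0, "frame": 0, "x_um": 2.0, "y_um": 0.0}])
        out = gold_truth_mean([a, b])
        assert (out.x_um[0], out.y_um[0]) == (1.0, 0.0)

    def test_missing_point_excluded(self):
        a = pd.DataFrame([
            {"track_id": 0, "frame": 0, "x_um": 0.0, "y_um": 0.0},
            {"track_id": 0, "frame": 1, "x_um": 1.0, "y_um": 0.0}])
        b = a.iloc[:1].copy()
        out = gold_truth_mean([a, b])
        assert len(out) == 1

    def test_consensus_error_shrinks_as_sqrt_k(self, rng):
        sigma = 2.0
        true = rng.uniform(0, 100, (1000, 2))
        frames = np.arange(1000)
        tables = []
        for _ in range(3):
            noisy = true + rng.normal(0, sigma, true.shape)
            tables.append(pd.DataFrame({
                "track_id": 0, "frame": frames,
                "x_um": noisy[:, 0], "y_um": noisy[:, 1]}))
        out = gold_truth_mean(tables).sort_values("frame")
        err = out[["x_um", "y_um"]].to_numpy() - true
        assert err.std() == pytest.approx(sigma / np.sqrt(3), rel=0.1)


class TestDistanceDistribution:
    def test_constant_offset(self):
        d = distance_distribution(np.full(200, 5.0))
        assert d.mode == pytest.approx(5.0, abs=1.0)
        assert d.fraction_above(10.0) == 0.0
        assert d.normalized.sum() == pytest.approx(100.0, abs=1e-9)

    def test_rayleigh_mode_and_tail(self, rng):
        sigma = 3.0
        dist = rng.rayleigh(sigma, 5000)
        d = distance_distribution(dist, bin_width=1.0)
        assert d.mode == pytest.approx(sigma, abs=0.5)   # Rayleigh mode = sigma
        tail = 100.0 * np.exp(-10.0 ** 2 / (2 * sigma ** 2))
        assert d.fraction_above(10.0) == pytest.approx(tail, abs=1.0)

    def test_fraction_above_close_to_direct_count(self, rng):
        vals = rng.rayleigh(4.0, 2000)
        d = distance_distribution(vals, bin_width=1.0)
        direct = 100.0 * (vals > 6.0).mean()
        one_bin_mass = d.normalized.max()
        assert abs(d.fraction_above(6.0) - direct) <= one_bin_mass


class TestVelocityAgreement:
    def test_identical_sets_zero_differences(self, rng):
        tracks = _random_tracks(rng, 6)
        pairs = match_track_sets(tracks, tracks)
        agr = velocity_agreement(pairs, dt=10.0)
        np.testing.assert_allclose(agr.differences, 0.0)
        assert agr.mean_difference == 0.0

    def test_constructed_offset_recovered(self, rng):
        tracks_a = _random_tracks(rng, 10, length=20)
        tracks_b = []
        for t in tracks_a:
            pts = t.positions.copy()
            # stretch every step so each is 0.5 µm longer (0.05 µm/min at
            # dt = 10), keeping start positions for matching
            steps = np.diff(pts, axis=0)
            norms = np.linalg.norm(steps, axis=1, keepdims=True)
            steps = steps * (norms + 0.5) / norms
            pts = np.vstack([pts[:1], pts[:1] + np.cumsum(steps, axis=0)])
            tracks_b.append(trajectory(pts, tid=t.id))
        pairs = match_track_sets(tracks_a, tracks_b)
        agr = velocity_agreement(pairs, dt=10.0)
        assert agr.mean_difference == pytest.approx(-0.05, abs=1e-9)

    def test_limits_contain_most_gaussian_differences(self, rng):
        tracks_a = _random_tracks(rng, 200, length=8, extent=3000.0)
        tracks_b = [trajectory(t.positions
                               + rng.normal(0, 0.8, t.positions.shape),
                               tid=t.id) for t in tracks_a]
        pairs = match_track_sets(tracks_a, tracks_b)
        agr = velocity_agreement(pairs, dt=10.0)
        lo, hi = agr.limits
        inside = ((agr.differences >= lo) & (agr.differences <= hi)).mean()
        assert inside >= 0.93


def test_tracks_from_table_round_trip(rng):
    tracks = _random_tracks(rng, 4)
    back = tracks_from_table(_table(tracks))
    assert [t.id for t in back] == [t.id for t in tracks]
    for a, b in zip(back, tracks):
        np.testing.assert_allclose(a.positions, b.positions)
        np.testing.assert_array_equal(a.frames, b.frames)


def test_tracks_from_table_rejects_missing_columns():
    with pytest.raises(ValueError, match="missing columns"):
        tracks_from_table(pd.DataFrame({"track_id": [], "frame": []}))
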