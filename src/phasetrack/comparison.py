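"""Cross-method trajectory comparison.

Track sets from two methods (or from this tool and manual annotation) are
matched one-to-one by the proximity of their first positions, point-to-
point separations on the common frames are binned into a 1 µm distance
distribution with a parabola-fitted mode, and per-track mean velocities
are compared Bland–Altman style.  A consensus "gold truth" can be formed
by averaging several independent manual annotations of the same cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_media import TRACK_TABLE_COLUMNS
from .metrics import VelocityDistribution, velocity_distribution
from .tracking import CellObservation, Track

logger = logging.getLogger(__name__)

__all__ = ["MatchedTrackPair", "match_track_sets", "gold_truth_mean",
           "distance_distribution", "velocity_agreement",
           "tracks_from_table"]


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    """Build tracks from the interchange schema (track_id, frame, x_um, y_um)."""
    missing = set(TRACK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"track table is missing columns {sorted(missing)}")
    tracks = []
    for tid, grp in table.groupby("track_id"):
        grp = grp.sort_values("frame")
        obs = [CellObservation(int(r.frame), float(r.x_um), float(r.y_um))
               for r in grp.itertuples()]
        tracks.append(Track(int(tid), obs))
    return tracks


@dataclass
class MatchedTrackPair:
    id_a: int
    id_b: int
    start_distance: float            # µm between first positions
    frames: np.ndarray               # common frame indices
    positions_a: np.ndarray          # (N, 2) µm
    positions_b: np.ndarray
    distances: np.ndarray            # per-frame point-to-point separation, µm


def _first(track: Track) -> np.ndarray:
    o = track.observations[0]
    return np.array([o.x, o.y])


def _aligned(a: Track, b: Track):
    fa = {int(o.frame_index): (o.x, o.y) for o in a.observations}
    fb = {int(o.frame_index): (o.x, o.y) for o in b.observations}
    common = sorted(fa.keys() & fb.keys())
    pa = np.array([fa[f] for f in common], dtype=float).reshape(-1, 2)
    pb = np.array([fb[f] for f in common], dtype=float).reshape(-1, 2)
    return np.asarray(common), pa, pb


def match_track_sets(tracks_a, tracks_b, threshold: float = 15.0
                     ) -> list[MatchedTrackPair]:
    """One-to-one matching of two track sets by first-position proximity.

    Pairs whose first positions are closer than ``threshold`` µm (default
    15) are accepted greedily in ascending order of that distance, with
    the same deterministic tie-break as the cell linker.  Per-frame
    separations are computed on the frames both tracks cover.
    """
    tracks_a = list(tracks_a)
    tracks_b = list(tracks_b)
    if not tracks_a or not tracks_b:
        return []
    starts_a = np.array([_first(t) for t in tracks_a])
    starts_b = np.array([_first(t) for t in tracks_b])
    d = np.linalg.norm(starts_a[:, None, :] - starts_b[None, :, :], axis=-1)
    ii, jj = np.nonzero(d < threshold)
    order = sorted(range(len(ii)), key=lambda k: (d[ii[k], jj[k]], ii[k], jj[k]))
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        frames, pa, pb = _aligned(tracks_a[i], tracks_b[j])
        pairs.append(MatchedTrackPair(
            id_a=tracks_a[i].id, id_b=tracks_b[j].id,
            start_distance=float(d[i, j]), frames=frames,
            positions_a=pa, positions_b=pb,
            distances=np.linalg.norm(pa - pb, axis=1)))
    return pairs


def gold_truth_mean(annotations: list[pd.DataFrame]) -> pd.DataFrame:
    """Consensus positions: the mean over k >= 2 annotations per (cell, frame).

    Each annotation uses the interchange schema with a shared cell
    numbering.  A (cell, frame) point missing from any annotator is
    excluded (and logged) rather than averaged over fewer observers.
    """
    if len(annotations) < 2:
        raise ValueError("gold truth needs at least two annotation sets")
    k = len(annotations)
    stacked = pd.concat(annotations, ignore_index=True)
    grouped = stacked.groupby(["track_id", "frame"], as_index=False).agg(
        x_um=("x_um", "mean"), y_um=("y_um", "mean"), n=("x_um", "size"))
    incomplete = grouped[grouped["n"] < k]
    if len(incomplete):
        logger.info("gold truth: excluded %d points missing from >=1 annotator",
                    len(incomplete))
    return grouped[grouped["n"] == k][TRACK_TABLE_COLUMNS].reset_index(drop=True)


def distance_distribution(pairs, bin_width: float = 1.0
                          ) -> VelocityDistribution:
    """1 µm-binned distribution of point-to-point separations.

    Pools the per-frame distances of all matched pairs; normalized so the
    sum is 100%, with the accumulated curve alongside.  The mode is the
    vertex of a parabola fitted to the peak (5 bins), and
    ``fraction_above(cutoff)`` interpolates linearly on the accumulated
    distribution — the 10 µm cutoff is the conventional "far miss" rate.
    """
    if hasattr(pairs, "__iter__") and not isinstance(pairs, np.ndarray):
        arrays = [p.distances for p in pairs] or [np.empty(0)]
        distances = np.concatenate(arrays)
    else:
        distances = np.asarray(pairs, dtype=float)
    if distances.size == 0:
        raise ValueError("no aligned distances to bin")
    return velocity_distribution(distances, bin_width)


@dataclass
class VelocityAgreement:
    """Bland–Altman comparison of per-track mean velocities (µm/min)."""

    differences: np.ndarray          # v_a - v_b per matched pair
    means: np.ndarray                # (v_a + v_b) / 2 per matched pair
    mean_difference: float
    sd_difference: float
    limits: tuple[float, float]      # mean ± 1.96 sd


def _mean_velocity(positions: np.ndarray, frames: np.ndarray, dt: float
                   ) -> float:
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    minutes = np.diff(frames) * dt
    return float(steps.sum() / minutes.sum())


def velocity_agreement(pairs, dt: float) -> VelocityAgreement:
    """Per-pair mean-velocity differences with 95% limits of agreement."""
    pairs = [p for p in pairs if len(p.frames) >= 2]
    if len(pairs) < 2:
        raise ValueError("velocity agreement needs >= 2 matched pairs")
    va = np.array([_mean_velocity(p.positions_a, p.frames, dt) for p in pairs])
    vb = np.array([_mean_velocity(p.positions_b, p.frames, dt) for p in pairs])
    diff = va - vb
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return VelocityAgreement(
        differences=diff, means=0.5 * (va + vb), mean_difference=mean_diff,
        sd_difference=sd,
        limits=(mean_diff - 1.96 * sd, mean_diff + 1.96 * sd))
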