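"""Frame-to-frame cell linking with gap repair and track smoothing.

Cells are linked between consecutive frames by a greedy least-displacement
rule: candidate pairs closer than the longest allowed step are sorted by
distance and accepted while both partners are free — the cells that moved
the least are matched first, as they are the most certain matches.  A cell
missed in exactly one frame is recovered by searching the unmatched cells
two frames back and inserting a synthetic observation midway between the
two detections.  A track ends after two consecutive unmatched frames.
Cell divisions are not detected: the nearest daughter simply continues the
track while the other starts a new one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import SegmentationResult
from .settings import Settings

__all__ = ["CellObservation", "Track", "TrackSet", "match_frames",
           "build_tracks", "smooth_track", "filter_valid_tracks"]


@dataclass(frozen=True)
class CellObservation:
    frame_index: int
    x: float                      # µm
    y: float                      # µm
    equivalent_diameter: float = 0.0
    repaired: bool = False        # inserted by gap repair, no underlying region


@dataclass
class Track:
    id: int
    observations: list[CellObservation] = field(default_factory=list)
    ended: bool = False

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) µm."""
        return np.array([(o.x, o.y) for o in self.observations], dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return np.array([o.frame_index for o in self.observations], dtype=int)

    @property
    def last(self) -> CellObservation:
        return self.observations[-1]


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)
    dt: float = 1.0               # minutes between frames

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self):
        return len(self.tracks)

    def n_observations(self) -> int:
        return sum(len(t) for t in self.tracks)


def match_frames(cells_now, cells_prev, max_step: float) -> dict[int, int]:
    """Greedy one-to-one matching: ``{now index -> prev index}``.

    All pairs with distance <= ``max_step`` (µm) are sorted ascending by
    distance — ties broken by smaller previous index, then smaller current
    index — and accepted greedily while both cells are unmatched.
    """
    now = np.asarray([(c.x, c.y) for c in cells_now], dtype=float)
    prev = np.asarray([(c.x, c.y) for c in cells_prev], dtype=float)
    if now.size == 0 or prev.size == 0:
        return {}
    d = np.linalg.norm(now[:, None, :] - prev[None, :, :], axis=-1)
    jj, ii = np.nonzero(d <= max_step)
    order = sorted(range(len(jj)), key=lambda k: (d[jj[k], ii[k]], ii[k], jj[k]))
    matched: dict[int, int] = {}
    used_prev: set[int] = set()
    for k in order:
        j, i = int(jj[k]), int(ii[k])
        if j in matched or i in used_prev:
            continue
        matched[j] = i
        used_prev.add(i)
    return matched


def _repair_matches(orphans, pending_heads, max_step: float) -> dict[int, int]:
    """Greedy matching of frame-t orphans against frame t-2 track heads,
    within twice the one-frame bound (the natural two-frame limit)."""
    return match_frames(orphans, pending_heads, 2.0 * max_step)


def build_tracks(frame_results, settings: Settings) -> TrackSet:
    """Link per-frame identified cells into a :class:`TrackSet`.

    ``frame_results`` is a sequence of per-frame
    :class:`~phasetrack.segmentation.SegmentationResult` (or plain lists
    of :class:`CellObservation`).  Every identified cell in every frame
    ends up in exactly one track; unmatched cells start new tracks
    (possibly of length 1).
    """
    dt = settings.effective_dt
    max_step = settings.max_step_um
    per_frame = []
    for t, fr in enumerate(frame_results):
        if isinstance(fr, SegmentationResult):
            obs = [CellObservation(t, c.centroid[0], c.centroid[1],
                                   c.equivalent_diameter)
                   for c in fr.identified]
        else:
            obs = [replace(o, frame_index=t) for o in fr]
        per_frame.append(obs)
    if len(per_frame) < 2:
        raise ValueError("tracking needs at least 2 segmented frames")

    next_id = 0
    tracks: list[Track] = []
    active: list[Track] = []      # last observation in frame t-1
    pending: list[Track] = []     # last observation in frame t-2 (one miss)

    def new_track(obs: CellObservation) -> Track:
        nonlocal next_id
        trk = Track(next_id, [obs])
        next_id += 1
        tracks.append(trk)
        return trk

    for obs in per_frame[0]:
        active.append(new_track(obs))

    for t in range(1, len(per_frame)):
        cells = per_frame[t]
        heads = [trk.last for trk in active]
        matched = match_frames(cells, heads, max_step)

        next_active: list[Track] = []
        claimed: set[int] = set()
        for j, i in matched.items():
            active[i].observations.append(cells[j])
            next_active.append(active[i])
            claimed.add(j)
        missed = [trk for i, trk in enumerate(active)
                  if i not in matched.values()]

        # gap repair: orphan cells vs tracks last seen two frames back
        orphans = [j for j in range(len(cells)) if j not in claimed]
        if pending and orphans:
            rep = _repair_matches([cells[j] for j in orphans],
                                  [trk.last for trk in pending], max_step)
            repaired_tracks: set[int] = set()
            for jo, ip in rep.items():
                j = orphans[jo]
                trk = pending[ip]
                prev = trk.last
                mid = CellObservation(
                    t - 1, 0.5 * (prev.x + cells[j].x),
                    0.5 * (prev.y + cells[j].y),
                    0.5 * (prev.equivalent_diameter
                           + cells[j].equivalent_diameter),
                    repaired=True)
                trk.observations.append(mid)
                trk.observations.append(cells[j])
                next_active.append(trk)
                claimed.add(j)
                repaired_tracks.add(ip)
            pending = [trk for i, trk in enumerate(pending)
                       if i not in repaired_tracks]

        for trk in pending:       # unmatched two frames in a row -> ended
            trk.ended = True
        pending = missed
        for j in range(len(cells)):
            if j not in claimed:
                next_active.append(new_track(cells[j]))
        active = next_active

    for trk in tracks:
        trk.ended = True
    return TrackSet(tracks, dt)


def smooth_track(track: Track, iterations: int) -> Track:
    """Low-pass filter a track with the (1/4, 1/2, 1/4) kernel.

    Each iteration replaces every interior position by the weighted
    average of its neighbours and itself; the start and end points remain
    fixed, so the Euclidean (net) displacement is preserved while small
    internal jitter — e.g. nuclear-speckle-driven centroid wobble in
    oversampled series — is damped.  Repaired flags are preserved.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or len(track) < 3:
        return Track(track.id, list(track.observations), track.ended)
    pos = track.positions
    for _ in range(iterations):
        interior = 0.25 * pos[:-2] + 0.5 * pos[1:-1] + 0.25 * pos[2:]
        pos = np.vstack([pos[:1], interior, pos[-1:]])
    obs = [replace(o, x=float(p[0]), y=float(p[1]))
           for o, p in zip(track.observations, pos)]
    return Track(track.id, obs, track.ended)


def filter_valid_tracks(track_set: TrackSet, shortest_cell_track: int
                        ) -> list[Track]:
    """Tracks with at least ``shortest_cell_track`` observations; only
    these enter migration metrics and overlays."""
    if shortest_cell_track < 2:
        raise ValueError("shortest_cell_track must be >= 2")
    return [t for t in track_set if len(t) >= shortest_cell_track]
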