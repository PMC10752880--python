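"""Migration measures per track, per time step and per video.

Definitions (all lengths µm, times minutes):

* accumulated distance — sum of step lengths along the track;
* Euclidean distance — straight-line start-to-end displacement;
* directness — Euclidean / accumulated, 1 for straight-line motion;
* forward migration index (FMI) — signed net displacement along one image
  axis divided by the accumulated distance.  FMIy is the vertical
  component (y grows downwards); in wound-healing mode its sign is
  flipped for tracks starting below the wound midline so that positive
  FMIy always means motion into the wound.

Degenerate denominators (a perfectly static track) yield NaN markers, not
zeros, so population summaries can skip them explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .registration import velocity_sum_per_cell
from .tracking import Track

__all__ = ["TrackMetrics", "FrameVelocitySummary", "VelocityDistribution",
           "compute_track_metrics", "wound_signed_fmi", "assign_wound_sides",
           "mean_velocity_over_time", "velocity_distribution",
           "count_cells_over_time", "step_velocities", "parabola_vertex"]


@dataclass(frozen=True)
class TrackMetrics:
    track_id: int
    n_steps: int
    duration: float                  # minutes
    mean_step_velocity: float        # µm/min
    accumulated_distance: float      # µm
    euclidean_distance: float        # µm
    euclidean_velocity: float        # µm/min
    directness: float                # dimensionless, in [0, 1]
    fmi_x: float
    fmi_y: float


@dataclass(frozen=True)
class FrameVelocitySummary:
    step_index: int                  # between frames step_index, step_index+1
    n_cells: int                     # identified cells in the later frame
    n_matched: int                   # valid-track steps spanning the pair
    mean_step_velocity: float        # µm/min (NaN if no steps)
    velocity_sum_per_cell: float     # µm/min (NaN if no steps)


def compute_track_metrics(track: Track, dt: float) -> TrackMetrics:
    """All per-track migration measures; requires >= 2 observations."""
    pos = track.positions
    if len(pos) < 2:
        raise ValueError("track metrics need at least 2 observations")
    steps = np.diff(pos, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    accumulated = float(lengths.sum())
    net = pos[-1] - pos[0]
    euclidean = float(np.hypot(*net))
    n_steps = len(lengths)
    duration = n_steps * dt
    if accumulated > 0:
        directness = euclidean / accumulated
        fmi_x = float(net[0]) / accumulated
        fmi_y = float(net[1]) / accumulated
    else:
        directness = fmi_x = fmi_y = float("nan")
    return TrackMetrics(
        track_id=track.id, n_steps=n_steps, duration=duration,
        mean_step_velocity=accumulated / duration,
        accumulated_distance=accumulated, euclidean_distance=euclidean,
        euclidean_velocity=euclidean / duration, directness=directness,
        fmi_x=fmi_x, fmi_y=fmi_y)


def assign_wound_sides(tracks) -> dict[int, str]:
    """Label each track 'top' or 'bottom' relative to the wound midline.

    The midline is the mean y of all track starting points — with crop
    margins set just outside a horizontal wound, the monolayer edges above
    and below the cell-free band straddle it symmetrically.
    """
    starts = {t.id: t.observations[0].y for t in tracks}
    if not starts:
        return {}
    midline = float(np.mean(list(starts.values())))
    return {tid: ("top" if y <= midline else "bottom")
            for tid, y in starts.items()}


def wound_signed_fmi(track_metrics: TrackMetrics, start_side: str
                     ) -> TrackMetrics:
    """Flip FMIy for bottom-edge tracks so positive means into the wound."""
    if start_side not in ("top", "bottom"):
        raise ValueError("start_side must be 'top' or 'bottom'")
    if start_side == "bottom":
        return replace(track_metrics, fmi_y=-track_metrics.fmi_y)
    return track_metrics


def step_velocities(tracks, dt: float) -> np.ndarray:
    """All per-step velocities (µm/min) of the given tracks, pooled."""
    out = []
    for t in tracks:
        lengths = np.linalg.norm(np.diff(t.positions, axis=0), axis=1)
        out.append(lengths / dt)
    return np.concatenate(out) if out else np.empty(0)


def mean_velocity_over_time(valid_tracks, dt: float, n_frames: int,
                            *, n_cells_per_frame=None
                            ) -> list[FrameVelocitySummary]:
    """Population velocity summary for every consecutive frame pair.

    For each pair the mean step velocity is taken over all valid-track
    steps spanning it, and the velocity-sum-per-cell misalignment
    diagnostic is computed from the same displacements.  Pairs with no
    steps yield NaN markers.
    """
    disp: dict[int, list] = {s: [] for s in range(n_frames - 1)}
    for trk in valid_tracks:
        frames = trk.frames
        pos = trk.positions
        for k in range(len(frames) - 1):
            disp[int(frames[k])].append(pos[k + 1] - pos[k])
    summaries = []
    for s in range(n_frames - 1):
        d = np.asarray(disp[s])
        n = len(d)
        if n:
            mean_v = float(np.mean(np.linalg.norm(d, axis=1)) / dt)
            vsum = velocity_sum_per_cell(d, dt)
        else:
            mean_v = vsum = float("nan")
        n_cells = (n_cells_per_frame[s + 1]
                   if n_cells_per_frame is not None else n)
        summaries.append(FrameVelocitySummary(s, int(n_cells), n, mean_v, vsum))
    return summaries


def two_stage_mean_velocity(summaries) -> float:
    """Overall mean velocity: first averaged for each time step, then
    averaged over all time steps (steps without data are skipped)."""
    vals = [s.mean_step_velocity for s in summaries
            if np.isfinite(s.mean_step_velocity)]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# histogram machinery shared with the comparison module


def parabola_vertex(centers: np.ndarray, counts: np.ndarray) -> float:
    """x-coordinate of the vertex of the least-squares quadratic through
    the given (center, count) points."""
    a, b, _ = np.polyfit(centers, counts, 2)
    if a >= 0:
        raise ValueError("peak fit is not concave")
    return float(-b / (2.0 * a))


@dataclass
class VelocityDistribution:
    """Binned distribution of step velocities (or any nonnegative lengths)."""

    bin_width: float
    edges: np.ndarray                # len = n_bins + 1
    counts: np.ndarray
    normalized: np.ndarray           # percent, sums to 100
    accumulated: np.ndarray          # percent, non-decreasing to 100
    mode: float                      # parabola vertex at the peak
    median: float                    # linear interpolation within the bin
    mean: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def fraction_above(self, cutoff: float) -> float:
        """Percent of values above ``cutoff``, by linear interpolation on
        the accumulated distribution."""
        grid = self.edges
        cum = np.concatenate([[0.0], self.accumulated])
        if cutoff <= grid[0]:
            return 100.0
        if cutoff >= grid[-1]:
            return 0.0
        return float(100.0 - np.interp(cutoff, grid, cum))


def velocity_distribution(values, bin_width: float, *,
                          fit_halfwidth: int = 2) -> VelocityDistribution:
    """Histogram with parabola-fitted mode and interpolated median.

    The mode is the vertex of a least-squares quadratic through the peak
    bin and ``fit_halfwidth`` neighbours on each side (5 bins by
    default).  A peak at the histogram edge (or a degenerate single-bin
    distribution) falls back to the peak-bin centre with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to bin")
    n_bins = max(int(np.ceil((values.max() + 1e-12) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    normalized = 100.0 * counts / counts.sum()
    accumulated = np.cumsum(normalized)
    centers = 0.5 * (edges[:-1] + edges[1:])

    p = int(np.argmax(counts))
    lo, hi = p - fit_halfwidth, p + fit_halfwidth + 1
    if lo < 0 or hi > n_bins:
        warnings.warn("distribution peak at histogram edge; "
                      "mode falls back to the peak-bin centre")
        mode = float(centers[p])
    else:
        try:
            mode = parabola_vertex(centers[lo:hi], counts[lo:hi])
        except ValueError:
            warnings.warn("non-concave peak fit; using peak-bin centre")
            mode = float(centers[p])

    # median: interpolate inside the bin where the accumulated % crosses 50
    k = int(np.searchsorted(accumulated, 50.0))
    below = accumulated[k - 1] if k > 0 else 0.0
    frac = (50.0 - below) / normalized[k] if normalized[k] > 0 else 0.5
    median = float(edges[k] + frac * bin_width)

    return VelocityDistribution(
        bin_width=bin_width, edges=edges, counts=counts,
        normalized=normalized, accumulated=accumulated, mode=mode,
        median=median, mean=float(values.mean()))


def count_cells_over_time(frame_results) -> np.ndarray:
    """Identified-cell count per frame (proliferation readout)."""
    return np.array([fr.n_identified for fr in frame_results], dtype=int)
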