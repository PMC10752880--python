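"""Summary plots: size histogram, velocity histogram with fitted parabola,
velocity over time, and trajectory plots (common origin and in place)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .io_media import track_colour
from .metrics import VelocityDistribution

__all__ = ["plot_size_histogram", "plot_velocity_histogram",
           "plot_velocity_over_time", "plot_trajectories"]


def _save(fig, path):
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_size_histogram(candidate_diameters, identified_diameters, path,
                        bin_width: float = 1.0):
    """Candidate (grey) vs identified (green) equivalent-diameter counts."""
    top = max(np.max(candidate_diameters, initial=1.0), 1.0)
    bins = np.arange(0, top + 2 * bin_width, bin_width)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(candidate_diameters, bins=bins, color="0.6", label="candidate cells")
    ax.hist(identified_diameters, bins=bins, color="forestgreen",
            label="identified cells")
    ax.set_xlabel("equivalent circular diameter (µm)")
    ax.set_ylabel("number of cells")
    ax.legend()
    _save(fig, path)


def plot_velocity_histogram(dist: VelocityDistribution, path):
    """Velocity histogram (red) with the parabola fitted at the peak (blue)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(dist.centers, dist.counts, color="crimson", label="velocity counts")
    p = int(np.argmax(dist.counts))
    lo, hi = max(p - 2, 0), min(p + 3, len(dist.counts))
    if hi - lo >= 3:
        coef = np.polyfit(dist.centers[lo:hi], dist.counts[lo:hi], 2)
        xs = np.linspace(dist.centers[lo], dist.centers[hi - 1], 50)
        ax.plot(xs, np.polyval(coef, xs), color="royalblue", label="peak fit")
    ax.axvline(dist.mode, color="royalblue", ls="--", lw=0.8)
    ax.set_xlabel("step velocity (µm/min)")
    ax.set_ylabel("number of steps")
    ax.legend()
    _save(fig, path)


def plot_velocity_over_time(summaries, dt: float, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.array([s.step_index for s in summaries]) * dt
    v = np.array([s.mean_step_velocity for s in summaries])
    ax.plot(t, v, "o-", color="crimson", ms=3)
    finite = v[np.isfinite(v)]
    if finite.size:
        ax.axhline(finite.mean(), color="k", lw=1)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("mean step velocity (µm/min)")
    _save(fig, path)


def plot_trajectories(tracks, path, *, common_origin: bool,
                      label_longest: int = 0):
    """Valid-track trajectories, either translated to a common origin or at
    their in-image positions (y axis inverted for display)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    lengths = sorted((len(t), t.id) for t in tracks)
    labelled = {tid for _, tid in lengths[-label_longest:]} if label_longest \
        else set()
    for trk in tracks:
        pos = trk.positions
        if common_origin:
            pos = pos - pos[0]
            colour = "crimson"
        else:
            colour = np.array(track_colour(trk.id)) / 255.0
        ax.plot(pos[:, 0], pos[:, 1], lw=0.8, color=colour)
        if trk.id in labelled:
            ax.annotate(str(trk.id), pos[-1], fontsize=7)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    _save(fig, path)
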