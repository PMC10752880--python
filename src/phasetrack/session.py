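"""Batch orchestration: per-video pipeline, output folders, run logging.

One call to :func:`process_video` runs the full pipeline on a single image
series — optional contrast reversal, lateral alignment, pseudo flat-field
correction, Gaussian smoothing, cropping, segmentation with concavity
cutting, greedy linking with gap repair, optional track smoothing, and all
migration metrics.  :func:`run_batch` maps it over many videos with
identical settings, writes one results folder per video plus a cross-video
summary table, and keeps going past per-video failures (which are logged).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_media, metrics, plots, preprocess, registration, segmentation, tracking
from .io_media import ImageStack
from .settings import Settings, save_settings

logger = logging.getLogger(__name__)

__all__ = ["VideoResult", "BatchResult", "process_video", "run_batch",
           "render_tuning_frame"]

OVERALL_COLUMNS = [
    "video", "n_frames", "n_cells_first", "n_cells_last", "n_tracks",
    "n_valid_tracks", "mean_velocity_um_min", "median_velocity_um_min",
    "mode_velocity_um_min", "mean_directness", "mean_fmi_x", "mean_fmi_y",
    "mean_accumulated_um", "mean_euclidean_um",
    "max_velocity_sum_per_cell_um_min",
]


@dataclass
class VideoResult:
    name: str
    settings: Settings
    stack: ImageStack
    shift_records: list = field(default_factory=list)
    frame_results: list = field(default_factory=list)   # SegmentationResult
    track_set: tracking.TrackSet | None = None
    valid_tracks: list = field(default_factory=list)
    track_metrics: list = field(default_factory=list)   # TrackMetrics
    frame_summaries: list = field(default_factory=list)
    velocity_dist: metrics.VelocityDistribution | None = None
    overall: dict = field(default_factory=dict)


def _nanmean(values) -> float:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    return float(arr.mean()) if arr.size else float("nan")


def process_video(source, settings: Settings, *, out_dir=None,
                  name: str | None = None) -> VideoResult:
    """Run the full pipeline on one video (path or :class:`ImageStack`)."""
    settings.validate()
    if isinstance(source, ImageStack):
        stack = source
        name = name or "stack"
    else:
        stack = io_media.read_stack(source, settings)
        name = name or Path(source).stem
    dt = stack.dt

    frames = stack.frames.astype(np.float64)
    if settings.contrast_reversal:
        frames = np.stack([preprocess.reverse_contrast(f) for f in frames])
        stack = stack.copy_with(frames)

    shift_records: list = []
    if settings.shift_correction:
        stack, shift_records = registration.align_stack(stack, settings)
        frames = stack.frames.astype(np.float64)

    if settings.flat_field_correction:
        frames = np.stack([
            preprocess.flat_field_correct(
                f, settings.flat_field_radius, settings.pixel_size,
                largest_cell_diameter=settings.largest_cell_diameter)
            for f in frames])

    frame_results = []
    for f in frames:
        smoothed = preprocess.gaussian_smooth(
            f, settings.gaussian_radius, settings.pixel_size)
        cropped, region = preprocess.crop(
            smoothed, settings.crop_top, settings.crop_bottom,
            settings.crop_left, settings.crop_right)
        frame_results.append(
            segmentation.segment_frame(cropped, settings, region=region))

    track_set = tracking.build_tracks(frame_results, settings)
    if settings.smoothing_iterations:
        track_set.tracks = [
            tracking.smooth_track(t, settings.smoothing_iterations)
            for t in track_set.tracks]
    valid = tracking.filter_valid_tracks(track_set, settings.shortest_cell_track)

    track_metrics = [metrics.compute_track_metrics(t, dt) for t in valid]
    if settings.wound_healing_mode:
        sides = metrics.assign_wound_sides(valid)
        track_metrics = [metrics.wound_signed_fmi(m, sides[m.track_id])
                         for m in track_metrics]

    counts = metrics.count_cells_over_time(frame_results)
    summaries = metrics.mean_velocity_over_time(
        valid, dt, stack.n_frames, n_cells_per_frame=counts)

    vel = metrics.step_velocities(valid, dt)
    vdist = None
    if vel.size:
        vdist = metrics.velocity_distribution(vel, settings.velocity_bin_width)

    vsums = [s.velocity_sum_per_cell for s in summaries]
    overall = {
        "video": name,
        "n_frames": stack.n_frames,
        "n_cells_first": int(counts[0]),
        "n_cells_last": int(counts[-1]),
        "n_tracks": len(track_set),
        "n_valid_tracks": len(valid),
        "mean_velocity_um_min": metrics.two_stage_mean_velocity(summaries),
        "median_velocity_um_min": vdist.median if vdist else float("nan"),
        "mode_velocity_um_min": vdist.mode if vdist else float("nan"),
        "mean_directness": _nanmean(m.directness for m in track_metrics),
        "mean_fmi_x": _nanmean(m.fmi_x for m in track_metrics),
        "mean_fmi_y": _nanmean(m.fmi_y for m in track_metrics),
        "mean_accumulated_um": _nanmean(
            m.accumulated_distance for m in track_metrics),
        "mean_euclidean_um": _nanmean(
            m.euclidean_distance for m in track_metrics),
        "max_velocity_sum_per_cell_um_min": max(
            (v for v in vsums if np.isfinite(v)), default=float("nan")),
    }

    result = VideoResult(
        name=name, settings=settings, stack=stack,
        shift_records=shift_records, frame_results=frame_results,
        track_set=track_set, valid_tracks=valid,
        track_metrics=track_metrics, frame_summaries=summaries,
        velocity_dist=vdist, overall=overall)

    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: VideoResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = result.settings
    dt = result.stack.dt
    # settings actually used, stored verbatim for future reference
    (out_dir / "settings_used.txt").write_text(save_settings(settings))

    io_media.write_tables(
        out_dir, track_metrics=result.track_metrics,
        tracks=result.valid_tracks, frame_summaries=result.frame_summaries,
        overall_row=result.overall, dt=dt)
    counts = metrics.count_cells_over_time(result.frame_results)
    pd.DataFrame({"frame": np.arange(len(counts)), "n_cells": counts}) \
        .to_csv(out_dir / "Cell_counts.csv", index=False)
    if result.shift_records:
        registration.shift_records_table(result.shift_records) \
            .to_csv(out_dir / "Shifts.csv", index=False)

    cand = [c.equivalent_diameter for fr in result.frame_results
            for c in fr.candidates]
    iden = [c.equivalent_diameter for fr in result.frame_results
            for c in fr.identified]
    if cand:
        plots.plot_size_histogram(cand, iden, out_dir / "Size_histogram.png")
    if result.velocity_dist is not None:
        plots.plot_velocity_histogram(result.velocity_dist,
                                      out_dir / "Velocity_histogram.png")
    plots.plot_velocity_over_time(result.frame_summaries, dt,
                                  out_dir / "Velocity_vs_time.png")
    if result.valid_tracks:
        plots.plot_trajectories(result.valid_tracks,
                                out_dir / "Trajectories_common_origin.png",
                                common_origin=True)
        plots.plot_trajectories(result.valid_tracks,
                                out_dir / "Trajectories_in_place.png",
                                common_origin=False, label_longest=5)

    outlines = []
    for fr in result.frame_results:
        mask = None
        if fr.labels is not None and fr.identified_labels:
            from skimage.segmentation import find_boundaries
            keep = np.isin(fr.labels, list(fr.identified_labels))
            bnd = find_boundaries(keep, mode="inner")
            full = np.zeros(result.stack.shape, dtype=bool)
            # labels live in the cropped region; place them back
            top = settings.crop_top
            left = settings.crop_left
            full[top:top + bnd.shape[0], left:left + bnd.shape[1]] = bnd
            mask = full
        outlines.append(mask)
    present = [t for t in result.valid_tracks]
    io_media.write_overlay_video(result.stack, out_dir / "Valid_tracks.tif",
                                 outlines=outlines, tracks=present)


@dataclass
class BatchResult:
    summary: pd.DataFrame
    results: list[VideoResult]
    failures: list[tuple[str, str]]          # (video, error message)
    log_path: Path | None = None


def run_batch(video_paths, settings: Settings, *, out_root=None) -> BatchResult:
    """Process many videos with identical settings.

    Each video gets a sibling results folder ``<video-stem>_results`` (or
    a folder under ``out_root``); a cross-video summary table holds one
    row per successfully processed video.  Decode or processing failures
    are logged and skipped; no readable videos at all is fatal.
    """
    paths = [Path(p) for p in video_paths]
    if not paths:
        raise ValueError("run_batch needs at least one video path")
    settings.validate()

    log_lines = [f"# phasetrack batch started {time.strftime('%Y-%m-%d %H:%M:%S')}",
                 "# settings:"]
    log_lines += ["#   " + line for line in save_settings(settings).splitlines()]

    rows, results, failures = [], [], []
    for path in paths:
        out_dir = (Path(out_root) / f"{path.stem}_results") if out_root \
            else path.parent / f"{path.stem}_results"
        t0 = time.time()
        try:
            res = process_video(path, settings, out_dir=out_dir)
        except Exception as exc:
            msg = f"{type(exc).__name__}: {exc}"
            failures.append((str(path), msg))
            logger.error("failed on %s: %s", path, msg)
            log_lines.append(f"FAILED {path}: {msg}")
            continue
        rows.append(res.overall)
        results.append(res)
        log_lines.append(
            f"OK {path} ({time.time() - t0:.1f} s, "
            f"{res.overall['n_valid_tracks']} valid tracks)")

    if not results:
        raise IOError("no video could be processed; see log for details")

    summary = pd.DataFrame(rows, columns=OVERALL_COLUMNS)
    log_path = None
    if out_root is not None:
        root = Path(out_root)
        root.mkdir(parents=True, exist_ok=True)
        summary.to_csv(root / "Batch_overall_summary.csv", index=False)
        log_path = root / "batch_log.txt"
        log_path.write_text("\n".join(log_lines) + "\n")
    return BatchResult(summary, results, failures, log_path)


def render_tuning_frame(source, settings: Settings, out_path) -> dict:
    """Render the first frame with candidate/identified overlays.

    A still-image stand-in for an interactive tuning window: candidate
    regions are outlined grey, identified cells green, and the grey limit
    is printed in the title, so threshold and size gates can be judged on
    one frame before a batch run.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    if isinstance(source, ImageStack):
        stack = source
    else:
        stack = io_media.read_stack(source, settings)
    frame = stack.frames[0].astype(np.float64)
    if settings.contrast_reversal:
        frame = preprocess.reverse_contrast(frame)
    if settings.flat_field_correction:
        frame = preprocess.flat_field_correct(
            frame, settings.flat_field_radius, settings.pixel_size,
            largest_cell_diameter=settings.largest_cell_diameter)
    smoothed = preprocess.gaussian_smooth(frame, settings.gaussian_radius,
                                          settings.pixel_size)
    cropped, region = preprocess.crop(
        smoothed, settings.crop_top, settings.crop_bottom,
        settings.crop_left, settings.crop_right)
    seg = segmentation.segment_frame(cropped, settings, region=region)

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(frame, cmap="gray", vmin=0, vmax=255)
    cand = find_boundaries(seg.labels > 0, mode="inner")
    keep = np.isin(seg.labels, list(seg.identified_labels)) \
        if seg.identified_labels else np.zeros_like(seg.labels, dtype=bool)
    iden = find_boundaries(keep, mode="inner")
    yy, xx = np.nonzero(cand)
    ax.plot(xx + region.left, yy + region.top, ".", color="0.6", ms=1)
    yy, xx = np.nonzero(iden)
    ax.plot(xx + region.left, yy + region.top, ".", color="lime", ms=1)
    ax.set_title(f"grey limit {seg.grey_limit:.1f}; "
                 f"{len(seg.identified)}/{len(seg.candidates)} identified")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return {"grey_limit": seg.grey_limit,
            "n_candidates": len(seg.candidates),
            "n_identified": len(seg.identified)}
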