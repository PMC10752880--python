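"""Reading image series and writing annotated videos and CSV tables.

The native lossless interchange format is multi-page TIFF; AVI input is
supported through whichever imageio video backend is installed.  All
processing happens on float frames holding 8-bit grey levels (0–255).
Positions reported anywhere in the package are micrometres with pixel
(0, 0) at the top-left, x rightward and y downward, measured at pixel
centres (``µm = pixel index × pixel_size``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .settings import Settings

__all__ = ["ImageStack", "read_stack", "write_stack", "write_overlay_video",
           "write_tables", "TRACK_TABLE_COLUMNS"]

# ITU-R 601 luma weights for colour -> grey conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageStack:
    """An ordered greyscale time-lapse: ``frames[t, y, x]`` in [0, 255]."""

    frames: np.ndarray        # (T, H, W) float32
    pixel_size: float         # µm per pixel
    dt: float                 # minutes between retained frames

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("an image stack needs >= 2 frames of equal shape")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite grey values in stack")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("pixel_size and dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def copy_with(self, frames: np.ndarray) -> "ImageStack":
        return ImageStack(frames, self.pixel_size, self.dt)


def _to_grey(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 4:           # (T, H, W, C)
        if frames.shape[-1] == 4:  # drop alpha
            frames = frames[..., :3]
        frames = frames.astype(np.float64) @ _LUMA
    return frames.astype(np.float32)


def _read_frames(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    try:
        import imageio.v3 as iio
        return np.stack(list(iio.imiter(path)))
    except Exception as exc:  # no backend for this container
        raise IOError(
            f"cannot decode {path}: {exc}. Export the series as multi-page "
            "TIFF, or install a video backend (e.g. imageio-ffmpeg) for AVI."
        ) from exc


def read_stack(path, settings: Settings) -> ImageStack:
    """Read an AVI or multi-page TIFF into a greyscale :class:`ImageStack`.

    Colour input is converted to luminance.  With ``skip_images = n`` every
    (n+1)-th frame is retained and the frame interval is scaled by (n+1),
    mimicking a series imaged at longer intervals.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no readable video at {path}")
    frames = _to_grey(_read_frames(path))
    if frames.ndim == 2:
        frames = frames[None]
    step = settings.skip_images + 1
    frames = frames[::step]
    if frames.shape[0] < 2:
        raise IOError(
            f"{path}: fewer than 2 frames retained (skip_images="
            f"{settings.skip_images})")
    return ImageStack(frames, settings.pixel_size, settings.effective_dt)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack losslessly as 8-bit multi-page TIFF."""
    data = np.clip(np.rint(stack.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data)


# ---------------------------------------------------------------------------
# overlay video

# distinct track colours, cycled (RGB 0-255)
_PALETTE = np.array([
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
    (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
], dtype=np.uint8)


def track_colour(track_id: int) -> tuple[int, int, int]:
    return tuple(int(c) for c in _PALETTE[track_id % len(_PALETTE)])


def write_overlay_video(stack: ImageStack, path, *, outlines=None,
                        tracks=None) -> None:
    """Write an RGB multi-page TIFF with cell outlines and track trails.

    Parameters
    ----------
    outlines : per-frame boolean masks of identified-cell boundary pixels,
        drawn in green.
    tracks : iterable of track objects (``id`` and ``observations`` with
        ``frame_index, x, y`` in µm).  Each track whose cell is present in
        the current frame is drawn as a coloured dot plus its polyline
        trail up to that frame; tracks already ended are not drawn.
    """
    from skimage.draw import disk, line

    T, (H, W) = stack.n_frames, stack.shape
    grey = np.clip(np.rint(stack.frames), 0, 255).astype(np.uint8)
    rgb = np.repeat(grey[..., None], 3, axis=-1)
    ps = stack.pixel_size

    if outlines is not None:
        for t, mask in enumerate(outlines):
            if mask is None:
                continue
            rgb[t][mask] = (0, 200, 0)

    if tracks:
        for trk in tracks:
            colour = track_colour(trk.id)
            obs = trk.observations
            px = [(int(round(o.x / ps)), int(round(o.y / ps))) for o in obs]
            for k, o in enumerate(obs):
                t = o.frame_index
                if not 0 <= t < T:
                    continue
                for (x0, y0), (x1, y1) in zip(px[:k], px[1:k + 1]):
                    rr, cc = line(y0, x0, y1, x1)
                    ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
                    rgb[t, rr[ok], cc[ok]] = colour
                rr, cc = disk((px[k][1], px[k][0]), 3, shape=(H, W))
                rgb[t, rr, cc] = colour

    tifffile.imwrite(path, rgb)


# ---------------------------------------------------------------------------
# CSV tables

TRACK_TABLE_COLUMNS = ["track_id", "frame", "x_um", "y_um"]

_PER_TRACK_COLUMNS = [
    "track_id", "n_steps", "duration_min", "mean_velocity_um_min",
    "accumulated_um", "euclidean_um", "euclidean_velocity_um_min",
    "directness", "fmi_x", "fmi_y", "length_frames",
]
_PER_STEP_COLUMNS = ["track_id", "frame", "x_um", "y_um",
                     "step_velocity_um_min", "repaired"]
_PER_FRAME_COLUMNS = ["step", "n_cells", "n_matched",
                      "mean_velocity_um_min", "velocity_sum_per_cell_um_min"]


def per_track_table(track_metrics) -> pd.DataFrame:
    """One row per valid track (see :class:`phasetrack.metrics.TrackMetrics`)."""
    rows = [{
        "track_id": m.track_id,
        "n_steps": m.n_steps,
        "duration_min": m.duration,
        "mean_velocity_um_min": m.mean_step_velocity,
        "accumulated_um": m.accumulated_distance,
        "euclidean_um": m.euclidean_distance,
        "euclidean_velocity_um_min": m.euclidean_velocity,
        "directness": m.directness,
        "fmi_x": m.fmi_x,
        "fmi_y": m.fmi_y,
        "length_frames": m.n_steps + 1,
    } for m in track_metrics]
    return pd.DataFrame(rows, columns=_PER_TRACK_COLUMNS)


def per_step_table(tracks, dt: float) -> pd.DataFrame:
    rows = []
    for trk in tracks:
        prev = None
        for o in trk.observations:
            v = np.nan
            if prev is not None:
                v = float(np.hypot(o.x - prev.x, o.y - prev.y)) / dt
            rows.append({"track_id": trk.id, "frame": o.frame_index,
                         "x_um": o.x, "y_um": o.y,
                         "step_velocity_um_min": v,
                         "repaired": bool(o.repaired)})
            prev = o
    return pd.DataFrame(rows, columns=_PER_STEP_COLUMNS)


def per_frame_table(frame_summaries) -> pd.DataFrame:
    rows = [{
        "step": s.step_index,
        "n_cells": s.n_cells,
        "n_matched": s.n_matched,
        "mean_velocity_um_min": s.mean_step_velocity,
        "velocity_sum_per_cell_um_min": s.velocity_sum_per_cell,
    } for s in frame_summaries]
    return pd.DataFrame(rows, columns=_PER_FRAME_COLUMNS)


def track_table(tracks) -> pd.DataFrame:
    """Interchange schema for cross-method comparison: track_id, frame, x, y."""
    rows = [{"track_id": trk.id, "frame": o.frame_index,
             "x_um": o.x, "y_um": o.y}
            for trk in tracks for o in trk.observations]
    return pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS)


def write_tables(out_dir, *, track_metrics, tracks, frame_summaries,
                 overall_row, dt: float) -> dict:
    """Write the per-track / per-step / per-frame / overall CSV suite.

    Decimal points are locale-independent (pandas always writes '.').
    Returns the mapping of table name to file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tables = {
        "Tracks": per_track_table(track_metrics),
        "Steps": per_step_table(tracks, dt),
        "Frames": per_frame_table(frame_summaries),
        "Overall_summary": pd.DataFrame([overall_row]),
        "Track_positions": track_table(tracks),
    }
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
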