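"""Synthetic phase-contrast-like time-lapse videos with exact ground truth.

The generator emulates the features of 10x Incucyte-S3 phase-contrast
imagery that the pipeline's assumptions rest on: a bright, fairly uniform
background; cell nuclei as smooth dark elliptical blobs; optional static
plate artefacts (the etched repositioning cross, collagen-like speckle);
global frame-to-frame jitter; and additive pixel noise.  Cells move by a
drift plus isotropic Brownian steps (per-axis standard deviation sigma, so
step lengths are Rayleigh distributed), reflecting at the borders, and may
divide.  Ground truth stores the pre-jitter ("world") positions, so
recovered cumulative alignment shifts can be compared with the injected
jitter list directly.

No optical physics is modelled (defocus, phase halos); realism extends
only as far as the segmentation assumptions require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_media import TRACK_TABLE_COLUMNS, ImageStack
from .registration import apply_fractional_shift

__all__ = ["SyntheticSpec", "CellTruth", "GroundTruth", "generate_video",
           "TrackingEvaluation", "evaluate_tracking"]


@dataclass
class SyntheticSpec:
    """Generator parameters (lengths µm unless noted)."""

    frame_shape: tuple[int, int] = (256, 256)   # (H, W) pixels
    pixel_size: float = 1.24                    # µm/px (Incucyte S3, 10x)
    n_frames: int = 30
    dt: float = 10.0                            # minutes
    n_cells: int = 20
    cell_diameter: float = 16.0                 # mean nominal diameter
    cell_diameter_sd: float = 2.0
    nucleus_depth: float = 60.0                 # grey levels below background
    background_grey: float = 150.0
    noise_sd: float = 3.0                       # grey levels
    sigma_step: float = 2.0                     # Brownian per-axis sd, µm/step
    drift: tuple[float, float] = (0.0, 0.0)     # µm/step
    jitter: list | None = None                  # per-frame (dx, dy) px
    cross_artifact: bool = False
    cross_depth: float = 12.0                   # grey levels
    cross_width: float = 150.0                  # µm (diffuse, plate-etching scale)
    speckle_density: float = 0.0                # static dark dots per µm²
    division_prob: float = 0.0                  # per cell per frame
    wound_band: tuple[float, float] | None = None  # cell-free y-range, µm
    wound_drift: float = 0.0                    # µm/step toward the wound
    min_separation_factor: float = 2.0          # placement spacing, diameters
    contact_factor: float = 0.9                 # excluded-volume distance, in
                                                # mean diameters (0 disables)
    boundary: str = "reflect"                   # "reflect" or "exit" (cells
                                                # leaving the frame disappear)
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.background_grey - self.nucleus_depth < 0:
            raise ValueError("nucleus depth exceeds background grey level")
        if self.sigma_step < 0 or self.noise_sd < 0:
            raise ValueError("sigma_step and noise_sd must be >= 0")
        H, W = self.frame_shape
        if self.cell_diameter / self.pixel_size > min(H, W):
            raise ValueError("cell diameter exceeds the frame")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.boundary not in ("reflect", "exit"):
            raise ValueError("boundary must be 'reflect' or 'exit'")
        return self


@dataclass
class CellTruth:
    id: int
    parent: int | None
    first_frame: int
    xs: list[float] = field(default_factory=list)   # µm, world coordinates
    ys: list[float] = field(default_factory=list)
    diameter: float = 0.0

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.xs) - 1

    def position_at(self, frame: int):
        k = frame - self.first_frame
        if 0 <= k < len(self.xs):
            return self.xs[k], self.ys[k]
        return None


@dataclass
class GroundTruth:
    cells: dict[int, CellTruth]
    n_frames: int
    pixel_size: float
    dt: float

    def positions_at(self, frame: int) -> dict[int, tuple[float, float]]:
        out = {}
        for cid, cell in self.cells.items():
            p = cell.position_at(frame)
            if p is not None:
                out[cid] = p
        return out

    def to_table(self) -> pd.DataFrame:
        rows = [{"track_id": cid, "frame": cell.first_frame + k,
                 "x_um": x, "y_um": y}
                for cid, cell in self.cells.items()
                for k, (x, y) in enumerate(zip(cell.xs, cell.ys))]
        return pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS)

    def step_lengths(self) -> np.ndarray:
        """All per-step displacements (µm) pooled over cells."""
        out = []
        for cell in self.cells.values():
            p = np.column_stack([cell.xs, cell.ys])
            if len(p) > 1:
                out.append(np.linalg.norm(np.diff(p, axis=0), axis=1))
        return np.concatenate(out) if out else np.empty(0)


class _Cell:
    __slots__ = ("id", "pos", "diameter", "aspect", "angle", "drift")

    def __init__(self, cid, pos, diameter, aspect, angle, drift):
        self.id = cid
        self.pos = np.asarray(pos, dtype=float)
        self.diameter = diameter
        self.aspect = aspect
        self.angle = angle
        self.drift = np.asarray(drift, dtype=float)


def _place_cells(spec: SyntheticSpec, rng) -> list[np.ndarray]:
    H, W = spec.frame_shape
    ps = spec.pixel_size
    margin = spec.cell_diameter
    min_sep = spec.min_separation_factor * spec.cell_diameter
    positions: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * max(spec.n_cells, 1)
    while len(positions) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.n_cells} cells with separation "
                f"{min_sep:.1f} µm in a {W * ps:.0f}x{H * ps:.0f} µm frame")
        p = np.array([rng.uniform(margin, W * ps - margin),
                      rng.uniform(margin, H * ps - margin)])
        if spec.wound_band is not None:
            lo, hi = spec.wound_band
            if lo - margin / 2 < p[1] < hi + margin / 2:
                continue
            # alternate sides so the monolayer edges are balanced
            want_top = len(positions) % 2 == 0
            if want_top != (p[1] <= lo):
                continue
        if positions and np.min(np.linalg.norm(
                np.asarray(positions) - p, axis=1)) < min_sep:
            continue
        positions.append(p)
    return positions


def _render_frame(cells: list[_Cell], spec: SyntheticSpec,
                  static_art: np.ndarray | None) -> np.ndarray:
    H, W = spec.frame_shape
    ps = spec.pixel_size
    frame = np.full((H, W), spec.background_grey, dtype=np.float64)
    if static_art is not None:
        frame -= static_art
    for cell in cells:
        # nucleus sigma = d/4: the dark blob spans roughly half the nominal
        # cell diameter, as the nucleus does in real phase-contrast frames
        sig_u = (cell.diameter / ps) / 4.0
        sig_v = sig_u * cell.aspect
        cx, cy = cell.pos / ps
        r = int(np.ceil(4 * sig_u))
        x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        c, s = np.cos(cell.angle), np.sin(cell.angle)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        q = (u / sig_u) ** 2 + (v / sig_v) ** 2
        frame[y0:y1, x0:x1] -= spec.nucleus_depth * np.exp(-0.5 * q)
    return frame


def _static_artifacts(spec: SyntheticSpec, rng) -> np.ndarray | None:
    H, W = spec.frame_shape
    ps = spec.pixel_size
    art = np.zeros((H, W), dtype=np.float64)
    have = False
    if spec.cross_artifact:
        # diffuse etched repositioning cross: Gaussian cross-section with
        # sigma = half the nominal width (plate etching is smooth-edged)
        s_px = max(spec.cross_width / ps / 2.0, 1.0)
        yy = np.arange(H) - H / 2.0
        xx = np.arange(W) - W / 2.0
        horiz = np.exp(-0.5 * (yy / s_px) ** 2)[:, None]
        vert = np.exp(-0.5 * (xx / s_px) ** 2)[None, :]
        art += spec.cross_depth * np.maximum(horiz, vert)
        have = True
    if spec.speckle_density > 0:
        n = rng.poisson(spec.speckle_density * H * W * ps * ps)
        yy = rng.uniform(0, H, n)
        xx = rng.uniform(0, W, n)
        for y, x in zip(yy, xx):
            y0, y1 = int(max(0, y - 2)), int(min(H, y + 3))
            x0, x1 = int(max(0, x - 2)), int(min(W, x + 3))
            gy, gx = np.mgrid[y0:y1, x0:x1]
            art[y0:y1, x0:x1] += 20.0 * np.exp(
                -((gx - x) ** 2 + (gy - y) ** 2) / (2 * 1.2 ** 2))
        have = True
    return art if have else None


def generate_video(spec: SyntheticSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a seeded synthetic time-lapse and its exact ground truth.

    Per frame: cells are rendered as Gaussian-profile dark ellipses on the
    bright background, static artefacts are composited, the whole frame is
    shifted by that frame's jitter, and pixel noise is added last.  The
    truth records pre-jitter centre positions.  The same seed always
    produces a bit-identical stack and truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.frame_shape
    ps = spec.pixel_size
    extent = np.array([W * ps, H * ps])
    margin = spec.cell_diameter / 2.0

    positions = _place_cells(spec, rng)
    cells: list[_Cell] = []
    truth: dict[int, CellTruth] = {}
    next_id = 0
    for p in positions:
        drift = np.asarray(spec.drift, dtype=float)
        if spec.wound_band is not None and spec.wound_drift:
            lo, hi = spec.wound_band
            toward = 1.0 if p[1] <= lo else -1.0   # move into the band
            drift = drift + np.array([0.0, toward * spec.wound_drift])
        d = max(rng.normal(spec.cell_diameter, spec.cell_diameter_sd),
                0.4 * spec.cell_diameter)
        cell = _Cell(next_id, p, d, rng.uniform(0.75, 1.0),
                     rng.uniform(0, np.pi), drift)
        cells.append(cell)
        truth[next_id] = CellTruth(next_id, None, 0, [p[0]], [p[1]],
                                   diameter=d)
        next_id += 1

    static_art = _static_artifacts(spec, rng)
    jitter = spec.jitter if spec.jitter is not None \
        else [(0.0, 0.0)] * spec.n_frames
    if len(jitter) < spec.n_frames:
        raise ValueError("jitter list shorter than n_frames")

    frames = np.empty((spec.n_frames, H, W), dtype=np.float32)

    def finish(t, world):
        jx, jy = jitter[t]
        if jx or jy:
            world = apply_fractional_shift(world, -jx, -jy)
        if spec.noise_sd > 0:
            world = world + rng.normal(0.0, spec.noise_sd, (H, W))
        frames[t] = np.clip(world, 0.0, 255.0)

    finish(0, _render_frame(cells, spec, static_art))

    for t in range(1, spec.n_frames):
        new_cells: list[_Cell] = []
        for cell in cells:
            if spec.division_prob > 0 and rng.uniform() < spec.division_prob:
                angle = rng.uniform(0, 2 * np.pi)
                offset = 0.6 * cell.diameter * np.array(
                    [np.cos(angle), np.sin(angle)])
                for sgn in (+1.0, -1.0):
                    q = np.clip(cell.pos + sgn * offset, margin,
                                extent - margin)
                    child = _Cell(next_id, q, cell.diameter,
                                  cell.aspect, cell.angle, cell.drift)
                    truth[next_id] = CellTruth(next_id, cell.id, t,
                                               [q[0]], [q[1]],
                                               diameter=cell.diameter)
                    new_cells.append(child)
                    next_id += 1
                continue
            others = np.array([c.pos for c in cells if c is not cell] +
                              [c.pos for c in new_cells]) \
                if spec.contact_factor else np.empty((0, 2))
            contact = spec.contact_factor * cell.diameter
            p = None
            for _ in range(8):   # excluded volume: nuclei cannot overlap
                q = cell.pos + cell.drift + rng.normal(0.0, spec.sigma_step, 2)
                if spec.boundary == "reflect":
                    # reflect at the borders so cells stay renderable
                    for ax in (0, 1):
                        lo, hi = margin, extent[ax] - margin
                        if q[ax] < lo:
                            q[ax] = 2 * lo - q[ax]
                        elif q[ax] > hi:
                            q[ax] = 2 * hi - q[ax]
                elif np.any(q < margin) or np.any(q > extent - margin):
                    p = None   # the cell leaves the field of view
                    break
                if len(others) == 0 or \
                        np.min(np.linalg.norm(others - q, axis=1)) >= contact:
                    p = q
                    break
            else:
                p = cell.pos         # crowded in: stay put this frame
            if p is None:
                continue             # exited: truth ends, cell not rendered
            cell.pos = p
            truth[cell.id].xs.append(p[0])
            truth[cell.id].ys.append(p[1])
            new_cells.append(cell)
        cells = new_cells
        finish(t, _render_frame(cells, spec, static_art))

    stack = ImageStack(frames, ps, spec.dt)
    return stack, GroundTruth(truth, spec.n_frames, ps, spec.dt)


# ---------------------------------------------------------------------------
# automated tracking audit against ground truth


@dataclass
class TrackingEvaluation:
    n_tracks: int
    n_truth_cells: int
    total_switches: int              # identity changes summed over tracks
    switches_per_track: dict[int, int]
    position_errors: np.ndarray      # µm, for every assigned observation
    fraction_assigned: float         # observations matched to a truth cell
    fraction_full_length: float      # truth cells recovered over their whole life


def evaluate_tracking(tracks, truth: GroundTruth, association_radius: float
                      ) -> TrackingEvaluation:
    """Audit a track set against ground truth.

    Every non-repaired observation is assigned to the nearest truth cell
    alive in that frame within ``association_radius`` µm.  Identity
    switches (a track's assignment changing between consecutive assigned
    observations) are counted per track and reported, not hidden; the
    pooled position errors and the fraction of truth cells recovered by a
    single track over their whole alive interval complete the audit.
    """
    tracks = list(tracks)
    cache = {t: truth.positions_at(t) for t in range(truth.n_frames)}
    switches_per_track: dict[int, int] = {}
    errors: list[float] = []
    n_obs = n_assigned = total_switches = 0
    coverage: dict[int, dict[int, set[int]]] = {}   # truth id -> track id -> frames

    for trk in tracks:
        prev_id = None
        switches = 0
        for o in trk.observations:
            if o.repaired:
                continue
            n_obs += 1
            alive = cache.get(o.frame_index, {})
            if not alive:
                continue
            ids = list(alive.keys())
            pts = np.array([alive[i] for i in ids])
            dist = np.linalg.norm(pts - np.array([o.x, o.y]), axis=1)
            k = int(np.argmin(dist))
            if dist[k] > association_radius:
                continue
            n_assigned += 1
            errors.append(float(dist[k]))
            tid = ids[k]
            coverage.setdefault(tid, {}).setdefault(trk.id, set()).add(
                o.frame_index)
            if prev_id is not None and tid != prev_id:
                switches += 1
            prev_id = tid
        switches_per_track[trk.id] = switches
        total_switches += switches

    full = 0
    for cid, cell in truth.cells.items():
        need = set(range(cell.first_frame, cell.last_frame + 1))
        by_track = coverage.get(cid, {})
        if any(need <= frames for frames in by_track.values()):
            full += 1

    return TrackingEvaluation(
        n_tracks=len(tracks), n_truth_cells=len(truth.cells),
        total_switches=total_switches, switches_per_track=switches_per_track,
        position_errors=np.asarray(errors),
        fraction_assigned=(n_assigned / n_obs) if n_obs else float("nan"),
        fraction_full_length=full / len(truth.cells) if truth.cells else
        float("nan"))
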