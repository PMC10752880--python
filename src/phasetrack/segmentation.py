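"""Grey-level segmentation of cell nuclei with concavity splitting.

After wide Gaussian smoothing every nucleus is one smooth dark blob on a
bright background, so segmentation reduces to a single grey-level limit:
all pixels darker than the limit are candidate-cell pixels.  Touching
nuclei merge into one connected region; those are cut apart along straight
lines drawn between nearby concave points of the region boundary (the
"neck" of the dumbbell).  Finally candidates are gated by their equivalent
circular diameter into identified cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.draw import line as draw_line

from .preprocess import CropRegion
from .settings import Settings

__all__ = ["CellRegion", "SegmentationResult", "determine_grey_limit",
           "threshold_and_label", "cut_touching_regions", "identify_cells",
           "segment_frame"]

_HALF_WIDTH = np.sqrt(2.0 * np.log(2.0))  # half-max offset of a Gaussian, in sigmas


@dataclass
class CellRegion:
    """A segmented candidate cell."""

    label: int
    area: int                       # pixels
    centroid: tuple[float, float]   # (x, y) µm, uncropped-frame coordinates
    equivalent_diameter: float      # µm, 2*sqrt(area_um2 / pi)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) px


@dataclass
class SegmentationResult:
    grey_limit: float
    candidates: list[CellRegion]
    identified: list[CellRegion]
    scrapped_too_small: int = 0
    scrapped_too_large: int = 0
    labels: np.ndarray | None = field(default=None, repr=False)
    identified_labels: set[int] = field(default_factory=set, repr=False)

    @property
    def n_identified(self) -> int:
        return len(self.identified)


def determine_grey_limit(frame: np.ndarray, segmentation_limit="auto",
                         *, k: float = 5.0) -> float:
    """Choose the grey level below which pixels belong to candidate cells.

    Manual mode (``segmentation_limit`` a negative number ``L``): limit =
    mean + L * sd of the smoothed frame's grey levels.

    Auto mode: the background is by far the dominant grey population and
    cells only *darken* pixels, so the histogram's main peak locates the
    background level and the bright flank of that peak (unreachable by
    cells) measures its half-width.  The limit is placed ``k`` background
    sigmas below the peak; with k = 5 (default) it sits just below the
    darkest cell-free background pixels (the expected minimum of ~1e6
    Gaussian background samples is about 4.9 sigma below the mean).
    """
    frame = np.asarray(frame, dtype=np.float64)
    sd = float(frame.std())
    if sd == 0:
        raise ValueError("no contrast: frame grey-level standard deviation is 0")
    if not (isinstance(segmentation_limit, str) and segmentation_limit == "auto"):
        limit = float(frame.mean()) + float(segmentation_limit) * sd
        return float(np.clip(limit, 0.0, 255.0))

    counts, edges = np.histogram(frame, bins=256, range=(0.0, 256.0))
    peak = int(np.argmax(counts))
    mu = 0.5 * (edges[peak] + edges[peak + 1])
    half = counts[peak] / 2.0
    bright = np.nonzero(counts[peak:] <= half)[0]
    if bright.size:
        # interpolate the half-max crossing for a stable width estimate
        i = peak + int(bright[0])
        if i > peak:
            frac = (counts[i - 1] - half) / max(counts[i - 1] - counts[i], 1)
            offset = i - peak - 1 + frac
        else:
            offset = 0.5
        sigma = max(offset / _HALF_WIDTH, 0.5)
    else:  # peak runs into the bright end; fall back to the global spread
        sigma = sd
    return float(np.clip(mu - k * sigma, 0.0, 255.0))


def threshold_and_label(frame: np.ndarray, grey_limit: float) -> np.ndarray:
    """Mark pixels darker than the limit and label 8-connected components.

    Components touching the border are kept — a cell half outside the
    analysis region may enter fully in later frames.
    """
    mask = np.asarray(frame) < grey_limit
    return measure.label(mask, connectivity=2)


# ---------------------------------------------------------------------------
# cutting of merged regions at concave boundary points

# Moore neighbourhood, clockwise on screen (y axis points down)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outer-boundary pixels of a single region (Moore tracing).

    ``mask`` must have a one-pixel false border.  Uses Jacob's stopping
    criterion: the walk ends when the start pixel is re-entered from the
    same direction as initially.
    """
    ys, xs = np.nonzero(mask)
    start = (int(ys[0]), int(xs[0]))       # topmost-leftmost pixel
    b, backtrack = start, (start[0], start[1] - 1)
    init = None
    boundary: list[tuple[int, int]] = []
    limit = 4 * (ys.size + 1)
    while len(boundary) <= limit:
        boundary.append(b)
        i = _MOORE.index((backtrack[0] - b[0], backtrack[1] - b[1]))
        nxt = None
        for step in range(1, 9):
            j = (i + step) % 8
            cand = (b[0] + _MOORE[j][0], b[1] + _MOORE[j][1])
            if mask[cand]:
                pj = (i + step - 1) % 8
                nxt = cand
                backtrack = (b[0] + _MOORE[pj][0], b[1] + _MOORE[pj][1])
                break
        if nxt is None:          # isolated pixel
            return boundary
        b = nxt
        state = (b, backtrack)
        if init is None:
            init = state
        elif state == init:
            return boundary
    return boundary


def _turning_angles(pts: np.ndarray, m: int) -> np.ndarray:
    """Signed turning angle at every boundary point over a ±m window."""
    v1 = pts - np.roll(pts, m, axis=0)
    v2 = np.roll(pts, -m, axis=0) - pts
    # pts are (row, col) = (y, x); cross_z = v1x*v2y - v1y*v2x
    cross = v1[:, 1] * v2[:, 0] - v1[:, 0] * v2[:, 1]
    dot = (v1 * v2).sum(axis=1)
    return np.arctan2(cross, dot)


def _neck_points(boundary: list[tuple[int, int]], m: int,
                 angle_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of concave local turning extrema and boundary arc lengths."""
    pts = np.asarray(boundary, dtype=np.float64)
    n = len(pts)
    seg = np.linalg.norm(pts - np.roll(pts, 1, axis=0), axis=1)
    arclen = np.cumsum(seg) - seg[0]
    if n < 2 * m + 1:
        return np.empty(0, dtype=int), arclen
    theta = _turning_angles(pts, m)
    orient = np.sign(_turning_angles(pts, 1).sum()) or 1.0
    concave = -orient * theta            # positive where the boundary dents in
    is_peak = (concave > angle_threshold) \
        & (concave >= np.roll(concave, 1)) & (concave >= np.roll(concave, -1))
    return np.nonzero(is_peak)[0], arclen


def _clear_line(mask: np.ndarray, p: tuple[int, int], q: tuple[int, int]) -> int:
    """Draw a background separation line from p to q (2 px thick so the
    cut also breaks 8-connectivity across diagonals).  Returns pixels cleared."""
    rr, cc = draw_line(p[0], p[1], q[0], q[1])
    if abs(q[1] - p[1]) >= abs(q[0] - p[0]):
        rr2, cc2 = rr + 1, cc            # mostly horizontal: thicken downwards
    else:
        rr2, cc2 = rr, cc + 1
    cleared = 0
    for r, c in zip(np.concatenate([rr, rr2]), np.concatenate([cc, cc2])):
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
            mask[r, c] = False
            cleared += 1
    return cleared


def cut_touching_regions(labels: np.ndarray, cutting_cell_diameter: float,
                         pixel_size: float, *, angle_threshold_deg: float = 35.0,
                         window: int | None = None, path_ratio: float = 2.0,
                         max_passes: int = 3) -> np.ndarray:
    """Split merged regions along lines between paired concave neck points.

    Only regions larger than one cutting-diameter disc are examined.  The
    boundary is traced with the Moore neighbourhood and the discrete
    turning angle computed over a ±``window`` step window (default
    ``max(3, round(0.25 * cutting_diameter_px))``).  Concave local extrema
    exceeding the angle threshold are neck candidates; two candidates are
    paired when their straight-line separation is below the cutting
    diameter while their boundary-path separation exceeds ``path_ratio``
    times the straight line (so a single bulge is never cut across).  The
    straight line between a paired set is set to background.  Up to
    ``max_passes`` passes let triplets split fully.
    """
    cut_d_px = cutting_cell_diameter / pixel_size
    area_limit = np.pi * (cut_d_px / 2.0) ** 2
    m = window if window is not None else max(3, round(0.25 * cut_d_px))
    thr = np.deg2rad(angle_threshold_deg)

    mask = np.asarray(labels) > 0
    for _ in range(max_passes):
        lab = measure.label(mask, connectivity=2)
        any_cut = False
        for region in measure.regionprops(lab):
            if region.area <= area_limit:
                continue
            r0, c0, r1, c1 = region.bbox
            sub = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
            sub[1:-1, 1:-1] = lab[r0:r1, c0:c1] == region.label
            boundary = _trace_boundary(sub)
            necks, arclen = _neck_points(boundary, m, thr)
            if necks.size < 2:
                continue
            pts = np.asarray(boundary, dtype=np.float64)
            total = arclen[-1] + np.linalg.norm(pts[-1] - pts[0])
            pairs = []
            for a_i, a in enumerate(necks):
                for b in necks[a_i + 1:]:
                    straight = float(np.linalg.norm(pts[a] - pts[b]))
                    if not 1.0 <= straight < cut_d_px:
                        continue
                    along = abs(arclen[a] - arclen[b])
                    path = min(along, total - along)
                    if path > path_ratio * straight:
                        pairs.append((straight, a, b))
            used: set[int] = set()
            for straight, a, b in sorted(pairs):
                if a in used or b in used:
                    continue
                pa = (boundary[a][0] + r0 - 1, boundary[a][1] + c0 - 1)
                pb = (boundary[b][0] + r0 - 1, boundary[b][1] + c0 - 1)
                if _clear_line(mask, pa, pb):
                    any_cut = True
                used.update((a, b))
        if not any_cut:
            break
    return measure.label(mask, connectivity=2)


# ---------------------------------------------------------------------------


def identify_cells(labels: np.ndarray, settings: Settings,
                   grey_limit: float, *,
                   region: CropRegion | None = None) -> SegmentationResult:
    """Gate candidate regions by equivalent circular diameter.

    Centroids are unweighted pixel-centre means reported in µm in the
    uncropped frame's coordinates (``region`` carries the crop offsets).
    The equivalent diameter is that of the circle with the region's area;
    it is generally smaller than the visible cell outline because only the
    dark nuclear blob is segmented.
    """
    ps = settings.pixel_size
    x_off = region.left if region else 0
    y_off = region.top if region else 0
    candidates: list[CellRegion] = []
    identified: list[CellRegion] = []
    identified_labels: set[int] = set()
    small = large = 0
    for rp in measure.regionprops(labels):
        cy, cx = rp.centroid
        d_um = 2.0 * np.sqrt(rp.area * ps * ps / np.pi)
        cell = CellRegion(
            label=rp.label, area=int(rp.area),
            centroid=((cx + x_off) * ps, (cy + y_off) * ps),
            equivalent_diameter=float(d_um), bbox=rp.bbox)
        candidates.append(cell)
        if d_um < settings.smallest_cell_diameter:
            small += 1
        elif d_um > settings.largest_cell_diameter:
            large += 1
        else:
            identified.append(cell)
            identified_labels.add(rp.label)
    return SegmentationResult(
        grey_limit=grey_limit, candidates=candidates, identified=identified,
        scrapped_too_small=small, scrapped_too_large=large, labels=labels,
        identified_labels=identified_labels)


def segment_frame(smoothed: np.ndarray, settings: Settings, *,
                  region: CropRegion | None = None,
                  grey_limit: float | None = None) -> SegmentationResult:
    """Full per-frame segmentation of an already smoothed (cropped) frame."""
    if grey_limit is None:
        grey_limit = determine_grey_limit(smoothed, settings.segmentation_limit)
    labels = threshold_and_label(smoothed, grey_limit)
    labels = cut_touching_regions(labels, settings.cutting_cell_diameter,
                                  settings.pixel_size)
    return identify_cells(labels, settings, grey_limit, region=region)
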