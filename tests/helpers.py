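"""Shared fixture builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from phasetrack.tracking import CellObservation


def disc_mask(shape, center, radius) -> np.ndarray:
    """Boolean disc: pixel centres within ``radius`` of ``center`` (y, x)."""
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 8-connected component count (BFS oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    H, W = mask.shape
    count = 0
    for sy in range(H):
        for sx in range(W):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            count += 1
            stack = [(sy, sx)]
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def brute_force_assignment(prev: np.ndarray, now: np.ndarray) -> dict[int, int]:
    """Minimum-total-distance one-to-one assignment by exhaustive search
    over all permutations (oracle for the greedy linker; equal sizes)."""
    from itertools import permutations

    n = len(prev)
    d = np.linalg.norm(now[:, None, :] - prev[None, :, :], axis=-1)
    best, best_perm = np.inf, None
    for perm in permutations(range(n)):
        total = d[np.arange(n), perm].sum()
        if total < best:
            best, best_perm = total, perm
    return {j: best_perm[j] for j in range(n)}


def observations(points, start_frame=0) -> list[CellObservation]:
    """Turn a list of (x, y) µm into one frame's worth of observations."""
    return [CellObservation(start_frame, float(x), float(y))
            for x, y in points]


def trajectory(points, tid=0, start_frame=0):
    """A Track visiting the given (x, y) µm points on consecutive frames."""
    from phasetrack.tracking import Track

    return Track(tid, [CellObservation(start_frame + i, float(x), float(y))
                       for i, (x, y) in enumerate(points)])


def walk_detections(rng, n_cells, n_frames, sigma, extent=3000.0,
                    drift=(0.0, 0.0)):
    """Per-frame detection lists for independent Gaussian random walks
    (no rendering, no borders) plus the per-cell true positions."""
    pos = rng.uniform(200.0, extent - 200.0, (n_cells, 2))
    truth = [pos.copy()]
    frames = [observations(pos)]
    for _ in range(1, n_frames):
        pos = pos + np.asarray(drift) + rng.normal(0.0, sigma, (n_cells, 2))
        truth.append(pos.copy())
        frames.append(observations(pos))
    return frames, np.asarray(truth)
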