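"""Contrast handling, pseudo flat-field correction, smoothing and cropping.

Cell nuclei appear as the darkest structures in 10x phase-contrast frames,
but they contain internal bright/dark speckle.  A wide Gaussian filter
smears the speckle into one smooth dark blob per nucleus so that a single
grey-level threshold can segment it.  The pseudo flat-field correction
removes static large-scale illumination structure (e.g. the etched
repositioning cross of imaging plates) that would otherwise segment as
spurious cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["reverse_contrast", "flat_field_correct", "gaussian_smooth",
           "crop", "CropRegion"]


def reverse_contrast(frame: np.ndarray) -> np.ndarray:
    """Invert grey levels (g -> 255 - g), for bright-cell imagery."""
    return 255.0 - np.asarray(frame, dtype=np.float64)


def flat_field_correct(frame: np.ndarray, background_radius: float,
                       pixel_size: float, *,
                       largest_cell_diameter: float | None = None
                       ) -> np.ndarray:
    """Subtract a large-scale Gaussian background estimate from the frame.

    The background is the frame blurred with sigma ``background_radius``
    (µm); the output is ``frame - background + mean(background)``, clipped
    to [0, 255].  Structures much wider than a cell are flattened while
    cell-scale contrast is preserved.  ``background_radius`` must clearly
    exceed the largest cell diameter, otherwise the correction would eat
    the cells themselves.
    """
    if largest_cell_diameter is not None and \
            background_radius <= largest_cell_diameter:
        raise ValueError(
            "flat-field background radius must exceed the largest cell "
            f"diameter ({background_radius} <= {largest_cell_diameter} µm)")
    frame = np.asarray(frame, dtype=np.float64)
    sigma = background_radius / pixel_size
    background = ndimage.gaussian_filter(frame, sigma, mode="nearest")
    corrected = frame - background + background.mean()
    return np.clip(corrected, 0.0, 255.0)


def gaussian_smooth(frame: np.ndarray, gaussian_radius: float,
                    pixel_size: float) -> np.ndarray:
    """Isotropic Gaussian filter with sigma = ``gaussian_radius`` µm.

    The "filter radius" is interpreted as the kernel standard deviation;
    at 0.645 µm/px a 10 µm radius is sigma ~= 15.5 px.  Reflective
    boundary handling keeps edge statistics unbiased.
    """
    if gaussian_radius <= 0:
        raise ValueError("gaussian_radius must be > 0")
    frame = np.asarray(frame, dtype=np.float64)
    return ndimage.gaussian_filter(frame, gaussian_radius / pixel_size,
                                   mode="reflect")


@dataclass(frozen=True)
class CropRegion:
    """Analysis region within the uncropped frame (pixel offsets)."""

    left: int
    top: int
    width: int
    height: int


def crop(frame: np.ndarray, crop_top: int, crop_bottom: int,
         crop_left: int, crop_right: int) -> tuple[np.ndarray, CropRegion]:
    """Cut the analysis region; downstream coordinates stay in the
    uncropped frame's µm system via the returned offsets."""
    H, W = frame.shape
    y0, y1 = crop_top, H - crop_bottom
    x0, x1 = crop_left, W - crop_right
    if y1 <= y0 or x1 <= x0:
        raise ValueError(
            f"crop margins leave an empty region on a {W}x{H} frame")
    return frame[y0:y1, x0:x1], CropRegion(x0, y0, x1 - x0, y1 - y0)
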