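"""Run settings: parsing, validation and persistence.

Settings live in a plain-text file with one ``Key = value`` pair per line,
using the key vocabulary of the original tool's defaults file.  Keys are
case-insensitive, whitespace around ``=`` is ignored, and both the ASCII
minus and the typographic en-dash/minus signs are accepted in numbers
(printed listings of the settings use the latter).
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field, fields

logger = logging.getLogger(__name__)

__all__ = ["Settings", "SettingsError", "load_settings", "save_settings"]


class SettingsError(ValueError):
    """A settings file could not be parsed or violates an invariant."""


#: sentinel for the automatic, background-based segmentation limit
AUTO = "auto"


@dataclass
class Settings:
    """All tunable parameters of a tracking run.

    Units: lengths in micrometres, times in minutes, crop margins in
    pixels, velocities in micrometres per minute.  ``segmentation_limit``
    is either the string ``"auto"`` (threshold derived from the background
    grey-level peak) or a negative number ``L`` selecting the manual rule
    ``limit = mean + L * sd`` on each smoothed frame.
    """

    pixel_size: float = 1.24            # µm per pixel (Incucyte S3, 10x)
    time_between_images: float = 10.0   # minutes
    gaussian_radius: float = 10.0       # µm, smoothing kernel sigma
    smallest_cell_diameter: float = 6.0
    largest_cell_diameter: float = 30.0
    cutting_cell_diameter: float = 20.0
    highest_cell_velocity: float = 10.0  # µm/min -> max step per frame
    shortest_cell_track: int = 5         # frames
    crop_top: int = 0
    crop_bottom: int = 0
    crop_left: int = 0
    crop_right: int = 0
    segmentation_limit: float | str = AUTO
    shift_correction: bool = False
    flat_field_correction: bool = False
    contrast_reversal: bool = False
    wound_healing_mode: bool = False
    skip_images: int = 0
    smoothing_iterations: int = 0
    random_seed: int = 0
    # advanced knobs (not part of the classic settings window)
    shift_search_radius: int = 20        # px, lateral alignment search bound
    flat_field_radius: float = 100.0     # µm, background blur scale
    velocity_bin_width: float = 0.05     # µm/min, velocity histogram bin

    def validate(self) -> "Settings":
        """Check all invariants; raise :class:`SettingsError` naming the key."""
        def positive(name):
            if getattr(self, name) <= 0:
                raise SettingsError(f"'{_CANONICAL[name]}' must be > 0")

        for name in ("pixel_size", "time_between_images", "gaussian_radius",
                     "highest_cell_velocity", "velocity_bin_width"):
            positive(name)
        if not 0 < self.smallest_cell_diameter < self.largest_cell_diameter:
            raise SettingsError(
                "'Smallest cell diameter' must be positive and smaller than "
                "'Largest cell diameter'")
        if not (self.smallest_cell_diameter <= self.cutting_cell_diameter
                <= self.largest_cell_diameter):
            raise SettingsError(
                "'Cutting cell diameter' must lie between the smallest and "
                "largest cell diameters")
        if self.shortest_cell_track < 2:
            raise SettingsError("'Shortest cell track' must be >= 2 frames")
        for name in ("crop_top", "crop_bottom", "crop_left", "crop_right",
                     "skip_images", "smoothing_iterations"):
            if getattr(self, name) < 0:
                raise SettingsError(f"'{_CANONICAL[name]}' must be >= 0")
        if self.shift_search_radius < 1:
            raise SettingsError("'Shift search radius' must be >= 1")
        if isinstance(self.segmentation_limit, str):
            if self.segmentation_limit != AUTO:
                raise SettingsError(
                    "'Segmentation limit' must be 'auto' or a negative number")
        elif self.segmentation_limit >= 0:
            raise SettingsError(
                "'Segmentation limit' must be negative (or 'auto')")
        return self

    @property
    def max_step_um(self) -> float:
        """Longest allowed cell displacement between retained frames (µm)."""
        return self.highest_cell_velocity * self.effective_dt

    @property
    def effective_dt(self) -> float:
        """Minutes between retained frames after image skipping."""
        return self.time_between_images * (self.skip_images + 1)

    def replace(self, **kwargs) -> "Settings":
        return dataclasses.replace(self, **kwargs).validate()


# canonical file keys, in the order they are written out
_CANONICAL = {
    "pixel_size": "Pixel size",
    "time_between_images": "Time between images",
    "gaussian_radius": "Gaussian filter radius",
    "smallest_cell_diameter": "Smallest cell diameter",
    "largest_cell_diameter": "Largest cell diameter",
    "cutting_cell_diameter": "Cutting cell diameter",
    "highest_cell_velocity": "Highest cell velocity",
    "shortest_cell_track": "Shortest cell track",
    "crop_top": "Top crop margin",
    "crop_bottom": "Bottom crop margin",
    "crop_left": "Left crop margin",
    "crop_right": "Right crop margin",
    "segmentation_limit": "Segmentation limit",
    "shift_correction": "Image shift correction",
    "flat_field_correction": "Flat-field correction",
    "contrast_reversal": "Contrast reversal",
    "wound_healing_mode": "Wound healing mode",
    "skip_images": "Skip images",
    "smoothing_iterations": "Smoothing iterations",
    "random_seed": "Random seed",
    "shift_search_radius": "Shift search radius",
    "flat_field_radius": "Flat field radius",
    "velocity_bin_width": "Velocity bin width",
}

# extra accepted spellings -> field name
_ALIASES = {
    "performflatfieldcorrection": "flat_field_correction",
    "flatfieldcorrection": "flat_field_correction",
    "shiftcorrection": "shift_correction",
    "segmentationlimit": "segmentation_limit",
    "tracksmoothingiterations": "smoothing_iterations",
}


def _norm_key(key: str) -> str:
    return re.sub(r"[^a-z0-9]", "", key.lower())


_KEYMAP = {_norm_key(v): k for k, v in _CANONICAL.items()} | _ALIASES

_TRUE = {"yes", "true", "on", "1", "y"}
_FALSE = {"no", "false", "off", "0", "n"}

# en dash, em dash and the Unicode minus all act as a minus sign
_MINUS = re.compile(r"[‐-―−]")


def _parse_number(text: str, lineno: int):
    cleaned = _MINUS.sub("-", text.strip())
    cleaned = re.sub(r"-\s+", "-", cleaned)  # "- 1.5" -> "-1.5"
    try:
        return float(cleaned)
    except ValueError:
        raise SettingsError(
            f"line {lineno}: cannot parse number from {text!r}") from None


def _coerce(name: str, raw: str, lineno: int):
    ftype = {f.name: f.type for f in fields(Settings)}[name]
    raw = raw.strip()
    if name == "segmentation_limit":
        if raw.lower() == AUTO:
            return AUTO
        return _parse_number(raw, lineno)
    if ftype == "bool":
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise SettingsError(f"line {lineno}: expected yes/no, got {raw!r}")
    if ftype == "int":
        value = _parse_number(raw, lineno)
        if value != int(value):
            raise SettingsError(f"line {lineno}: expected an integer, got {raw!r}")
        return int(value)
    return _parse_number(raw, lineno)


def load_settings(text: str) -> Settings:
    """Parse settings-file content into a validated :class:`Settings`.

    Unknown keys produce a warning and are otherwise ignored; blank lines
    and ``#`` comments are allowed.  Every absent key keeps its documented
    default, so empty text yields the all-default configuration.
    """
    values: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise SettingsError(f"line {lineno}: expected 'Key = value'")
        key, _, raw = stripped.partition("=")
        name = _KEYMAP.get(_norm_key(key))
        if name is None:
            logger.warning("ignoring unknown settings key %r (line %d)",
                           key.strip(), lineno)
            continue
        values[name] = _coerce(name, raw, lineno)
    return Settings(**values).validate()


def save_settings(settings: Settings) -> str:
    """Render settings as canonical ``Key = value`` text (load/save round-trips)."""
    lines = []
    for name, key in _CANONICAL.items():
        value = getattr(settings, name)
        if isinstance(value, bool):
            value = "yes" if value else "no"
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"
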