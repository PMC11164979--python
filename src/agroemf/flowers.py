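"""Flower-abundance estimation by per-pixel RGB threshold classification.

Pixels are assigned to one of six flower color classes by fixed threshold
rules on the 8-bit RGB channels, evaluated in a fixed order with first match
winning.  The rules use strict inequalities throughout.  Note that the
violet rule is unsatisfiable as written (it requires r < 100, b > 150 and
|r - b| < 50 simultaneously, but those bounds force b - r > 50); it is kept
literally for fidelity and documented as matching zero pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._errors import ConfigurationError, DomainError

#: Class evaluation order; first match wins.
FLOWER_CLASSES: tuple[str, ...] = ("red", "orange", "blue", "violet", "white", "yellow")


def classify_pixel(r: int, g: int, b: int) -> str | None:
    """Classify one RGB pixel into a flower color class, or ``None``.

    Channels must be in 0..255.  Rules (strict inequalities, first match):

    - red:    r > 200 and g < 100 and b < 100
    - orange: r > 200 and g > 100 and 50 < b < 150
    - blue:   r < 100 and g < 100 and b > 200
    - violet: r < 100 and g < 100 and b > 150 and |r - b| < 50
    - white:  r > 200 and g > 200 and b > 200
    - yellow: r > 200 and g > 200 and b < 100
    """
    for name, chan in (("r", r), ("g", g), ("b", b)):
        if not 0 <= chan <= 255:
            raise DomainError(f"channel {name}={chan} outside 0..255")
    if r > 200 and g < 100 and b < 100:
        return "red"
    if r > 200 and g > 100 and 50 < b < 150:
        return "orange"
    if r < 100 and g < 100 and b > 200:
        return "blue"
    if r < 100 and g < 100 and b > 150 and abs(r - b) < 50:
        return "violet"
    if r > 200 and g > 200 and b > 200:
        return "white"
    if r > 200 and g > 200 and b < 100:
        return "yellow"
    return None


def class_masks(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized class predicates mirroring :func:`classify_pixel`.

    Returns boolean arrays with first-match precedence applied (the rules
    are provably disjoint, but determinism is cheap to guarantee).
    """
    r = r.astype(np.int16)
    g = g.astype(np.int16)
    b = b.astype(np.int16)
    rules = {
        "red": (r > 200) & (g < 100) & (b < 100),
        "orange": (r > 200) & (g > 100) & (b > 50) & (b < 150),
        "blue": (r < 100) & (g < 100) & (b > 200),
        "violet": (r < 100) & (g < 100) & (b > 150) & (np.abs(r - b) < 50),
        "white": (r > 200) & (g > 200) & (b > 200),
        "yellow": (r > 200) & (g > 200) & (b < 100),
    }
    taken = np.zeros_like(rules["red"])
    masks = {}
    for cls in FLOWER_CLASSES:
        masks[cls] = rules[cls] & ~taken
        taken |= rules[cls]
    return masks


@dataclass
class ColorCounts:
    """Per-class flower pixel counts for one image."""

    counts: dict[str, int]
    total_pixels: int
    masked_pixels: int = 0
    source: str | None = None

    def __post_init__(self) -> None:
        if self.total_pixels <= 0:
            raise DomainError("image has no pixels")
        if sum(self.counts.values()) > self.total_pixels:
            raise DomainError("class counts exceed total pixel count")

    @property
    def flower_pixels(self) -> int:
        return sum(self.counts.values())

    @property
    def flower_fraction(self) -> float:
        """Share of flower pixels over the *full* pixel count (masked included)."""
        return self.flower_pixels / self.total_pixels

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"filename": self.source or ""}
        row.update({cls: self.counts.get(cls, 0) for cls in FLOWER_CLASSES})
        row["total_pixels"] = self.total_pixels
        row["flower_percent"] = 100.0 * self.flower_fraction
        return row


def _to_rgb_array(image) -> np.ndarray:
    """Coerce a PIL image, path, or HxWx3(4) array to an HxWx3 uint8 array."""
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        arr = np.asarray(image.convert("RGBA"))[:, :, :3]
    else:
        arr = np.asarray(image)
        if arr.ndim != 3 or arr.shape[2] not in (3, 4):
            raise ConfigurationError("expected an HxWx3 or HxWx4 pixel array")
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise DomainError("channel values outside 0..255")
        arr = arr.astype(np.uint8)
    return arr


def flower_fraction(image, mask: np.ndarray | None = None) -> ColorCounts:
    """Count flower-colored pixels in an image.

    Parameters
    ----------
    image:
        PIL image, path to a PNG/JPEG file, or HxWx3(4) uint8 array.
    mask:
        Optional HxW boolean array; ``True`` positions are blacked out
        (set to RGB 0,0,0) before counting, so they can never match a
        flower class — but they *remain in the denominator*, matching the
        manual blackout-then-count procedure.

    Returns
    -------
    :class:`ColorCounts` with per-class counts and the overall fraction.
    """
    arr = _to_rgb_array(image)
    h, w = arr.shape[:2]
    if h == 0 or w == 0:
        raise DomainError("image has no pixels")
    masked = 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ConfigurationError(
                f"mask shape {mask.shape} does not match image shape {(h, w)}"
            )
        arr = arr.copy()
        arr[mask] = 0
        masked = int(mask.sum())
    r, g, b = arr[:, :, 0], arr[:, :, 1], arr[:, :, 2]
    masks = class_masks(r, g, b)
    counts = {cls: int(m.sum()) for cls, m in masks.items()}
    source = str(image) if isinstance(image, (str, Path)) else None
    return ColorCounts(counts=counts, total_pixels=h * w, masked_pixels=masked, source=source)


def annotate_image(image, mask: np.ndarray | None = None) -> Image.Image:
    """Return an RGBA copy with non-flower pixels dimmed for visual audit."""
    arr = _to_rgb_array(image)
    if mask is not None:
        arr = arr.copy()
        arr[np.asarray(mask, dtype=bool)] = 0
    masks = class_masks(arr[:, :, 0], arr[:, :, 1], arr[:, :, 2])
    any_flower = np.zeros(arr.shape[:2], dtype=bool)
    for m in masks.values():
        any_flower |= m
    rgba = np.dstack([arr, np.where(any_flower, 255, 80).astype(np.uint8)])
    return Image.fromarray(rgba, mode="RGBA")


def classify_directory(
    image_dir, pattern: str = "*.png", masks: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Classify every image matching ``pattern`` in a directory.

    Returns one row per image (filename, per-class counts, flower percent).
    """
    image_dir = Path(image_dir)
    rows = []
    for path in sorted(image_dir.glob(pattern)):
        mask = (masks or {}).get(path.name)
        counts = flower_fraction(path, mask=mask)
        row = counts.as_row()
        row["filename"] = path.name
        rows.append(row)
    return pd.DataFrame(rows)
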