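"""Radiograph preprocessing: CLAHE contrast enhancement and
ratio-preserving standardization to a square grid (default 512 x 512).

Standardization scales the long side to the target, preserving aspect
ratio, and zero-pads the short side symmetrically.  The affine mapping
(scale + offsets) is recorded so measurements made on the standardized
grid can be mapped back to original pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage import exposure, transform

from .errors import ValidationError

__all__ = [
    "RadiographImage",
    "StandardizeAffine",
    "apply_clahe",
    "standardize",
    "load_image",
]

DEFAULT_TARGET_SIZE = 512
DEFAULT_CLIP_LIMIT = 0.02      # normalized CLAHE clip limit
DEFAULT_TILE_GRID = (8, 8)


@dataclass
class RadiographImage:
    """A 2D intensity raster with optional pixel-spacing metadata."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(
                f"radiograph must be a non-empty 2D raster, got shape "
                f"{self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValidationError("radiograph contains non-finite intensities")
        if self.pixels.min() < 0:
            raise ValidationError("radiograph contains negative intensities")


@dataclass
class StandardizeAffine:
    """Mapping original -> standardized coordinates: std = orig * scale + offset."""

    scale: float
    row_offset: float
    col_offset: float

    def to_standardized(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts * self.scale + np.array([self.row_offset, self.col_offset])

    def to_original(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - np.array([self.row_offset, self.col_offset])) / self.scale


def _normalize01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def apply_clahe(img, clip_limit: float = DEFAULT_CLIP_LIMIT,
                tile_grid: tuple[int, int] = DEFAULT_TILE_GRID):
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is the normalized clipping threshold in (0, 1];
    ``tile_grid`` is the number of contextual tiles per axis.  Returns an
    image of the same shape with intensities in [0, 1].  Accepts either a
    :class:`RadiographImage` or a bare array; returns the matching type.
    """
    if clip_limit <= 0:
        raise ValidationError(f"clip_limit must be > 0, got {clip_limit}")
    if tile_grid[0] < 1 or tile_grid[1] < 1:
        raise ValidationError(f"tile_grid dims must be >= 1, got {tile_grid}")
    is_obj = isinstance(img, RadiographImage)
    arr = img.pixels if is_obj else np.asarray(img, dtype=np.float32)
    if not np.isfinite(arr).all():
        raise ValidationError("input contains non-finite intensities")
    if arr.max() == arr.min():
        out = arr.astype(np.float32).copy()          # no local contrast to amplify
    else:
        kernel = (max(arr.shape[0] // tile_grid[0], 1),
                  max(arr.shape[1] // tile_grid[1], 1))
        out = exposure.equalize_adapthist(_normalize01(arr), kernel_size=kernel,
                                          clip_limit=clip_limit).astype(np.float32)
    if is_obj:
        return RadiographImage(out, img.pixel_spacing, img.source_id)
    return out


def standardize(arr: np.ndarray, target: int = DEFAULT_TARGET_SIZE,
                is_mask: bool = False) -> tuple[np.ndarray, StandardizeAffine]:
    """Scale the long side to ``target`` (aspect preserved) and zero-pad.

    Images are resampled bilinearly; masks nearest-neighbour, so binary
    masks stay binary.  Returns the standardized raster and the recorded
    affine.  Already-target-sized inputs pass through with an identity
    affine.
    """
    arr = np.asarray(arr)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"expected a non-empty 2D raster, got shape {arr.shape}")
    h, w = arr.shape
    if (h, w) == (target, target):
        return arr.copy(), StandardizeAffine(1.0, 0.0, 0.0)
    scale = target / max(h, w)
    new_h, new_w = int(round(h * scale)), int(round(w * scale))
    if is_mask:
        resized = transform.resize(arr.astype(np.float32), (new_h, new_w), order=0,
                                   anti_aliasing=False, preserve_range=True)
        resized = (resized > 0.5).astype(arr.dtype if arr.dtype != bool else np.uint8)
    else:
        resized = transform.resize(arr.astype(np.float32), (new_h, new_w), order=1,
                                   anti_aliasing=scale < 1, preserve_range=True
                                   ).astype(np.float32)
    row_off = (target - new_h) // 2
    col_off = (target - new_w) // 2
    out = np.zeros((target, target), dtype=resized.dtype)
    out[row_off:row_off + new_h, col_off:col_off + new_w] = resized
    return out, StandardizeAffine(scale, float(row_off), float(col_off))


def load_image(path, source_id: str | None = None) -> RadiographImage:
    """Read a PNG/TIFF raster as a float radiograph (collapses RGB to gray)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return RadiographImage(arr.astype(np.float32),
                           source_id=source_id or str(path))
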