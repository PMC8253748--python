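"""Synthetic spine phantom generator.

Builds a vertical stack of convex quadrilateral "vertebral bodies" on a
blank canvas, together with a pseudo-radiograph rendering and exact
ground-truth annotations (corner coordinates, anterior heights, true
compression percentages).  Anterior is the left side of the image, the
lateral-radiograph convention.  Compression is modelled as anterior
wedging: the upper-left corner of a body is lowered by the requested
fraction of the body height, which shortens the anterior edge without
breaking convexity.

The generator is fully deterministic given its seed, so every downstream
stage (segmentation, division, geometric and learned measurement) can be
exercised and scored against exact truth without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ConfigurationError, ValidationError
from .geometry import compute_vc

__all__ = [
    "PhantomSpec",
    "VertebraTruth",
    "PhantomTruth",
    "generate_phantom",
    "degrade_mask",
    "write_phantom",
]

# rendering intensities for the pseudo-radiograph (fractions of dynamic range)
_BODY_INTENSITY = 0.7
_BACKGROUND_INTENSITY = 0.3


@dataclass
class PhantomSpec:
    """Parameters of one synthetic spine phantom.

    ``compression_map`` maps a 1-based vertebra label (1 = topmost) to an
    anterior height-loss fraction in [0, 0.6].  ``tilt_deg`` is either a
    single in-plane rotation applied to every body or a per-label mapping.
    """

    n_vertebrae: int = 4
    canvas_size: tuple[int, int] = (512, 512)
    base_height: int = 96
    base_width: int = 120
    gap: int = 12
    compression_map: Mapping[int, float] = field(default_factory=dict)
    tilt_deg: float | Mapping[int, float] = 0.0
    noise_sigma: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_vertebrae < 3:
            raise ConfigurationError(
                f"n_vertebrae must be >= 3 (got {self.n_vertebrae}): a "
                "compression measurement needs a three-body window")
        if self.gap < 1:
            raise ConfigurationError(
                f"gap must be >= 1 pixel so bodies stay disjoint (got {self.gap})")
        rows, cols = self.canvas_size
        if self.n_vertebrae * (self.base_height + self.gap) > rows:
            raise ConfigurationError(
                f"stack does not fit on canvas: {self.n_vertebrae} x "
                f"({self.base_height} + {self.gap}) > {rows} rows")
        if self.base_width + 2 > cols:
            raise ConfigurationError(
                f"base_width {self.base_width} does not fit in {cols} columns")
        for lbl, frac in self.compression_map.items():
            if not (1 <= lbl <= self.n_vertebrae):
                raise ConfigurationError(
                    f"compression_map label {lbl} outside 1..{self.n_vertebrae}")
            if not (0.0 <= frac <= 0.6):
                raise ConfigurationError(
                    f"compression fraction {frac} for vertebra {lbl} outside [0, 0.6]")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0 (got {self.noise_sigma})")

    def tilt_for(self, label: int) -> float:
        if isinstance(self.tilt_deg, Mapping):
            return float(self.tilt_deg.get(label, 0.0))
        return float(self.tilt_deg)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "canvas_size" in raw:
            raw["canvas_size"] = tuple(raw["canvas_size"])
        if "compression_map" in raw:
            raw["compression_map"] = {int(k): float(v)
                                      for k, v in raw["compression_map"].items()}
        return cls(**raw)


@dataclass
class VertebraTruth:
    """Exact annotation for one phantom vertebra.

    ``corners`` is a (4, 2) float array of (row, col) points in the order
    upper-left, upper-right, lower-right, lower-left.  ``true_vc_pct`` is
    None for the topmost and bottommost bodies, which have no complete
    neighbour pair.
    """

    label: int
    corners: np.ndarray
    anterior_height: float
    true_vc_pct: float | None = None

    @property
    def left_pair(self) -> np.ndarray:
        """Anterior (left) corners: upper-left and lower-left."""
        return self.corners[[0, 3]]


@dataclass
class PhantomTruth:
    vertebrae: list[VertebraTruth]

    def __getitem__(self, label: int) -> VertebraTruth:
        for v in self.vertebrae:
            if v.label == label:
                return v
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.vertebrae:
            row: dict = {"vertebra_id": v.label}
            for i in range(4):
                row[f"corner{i + 1}_row"] = v.corners[i, 0]
                row[f"corner{i + 1}_col"] = v.corners[i, 1]
            row["anterior_height_px"] = v.anterior_height
            row["true_vc_pct"] = np.nan if v.true_vc_pct is None else v.true_vc_pct
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhantomTruth":
        verts = []
        for _, r in df.iterrows():
            corners = np.array([[r[f"corner{i + 1}_row"], r[f"corner{i + 1}_col"]]
                                for i in range(4)], dtype=float)
            vc = None if pd.isna(r["true_vc_pct"]) else float(r["true_vc_pct"])
            verts.append(VertebraTruth(int(r["vertebra_id"]), corners,
                                       float(r["anterior_height_px"]), vc))
        return cls(verts)


def _body_corners(spec: PhantomSpec, index: int,
                  subpixel_shift: np.ndarray | None = None) -> np.ndarray:
    """Exact corner coordinates (UL, UR, LR, LL) for body ``index`` (0-based)."""
    h, w = float(spec.base_height), float(spec.base_width)
    label = index + 1
    frac = float(spec.compression_map.get(label, 0.0))
    # anterior wedging: the upper-left corner drops by frac * h
    local = np.array([[frac * h, 0.0],
                      [0.0, w],
                      [h, w],
                      [h, 0.0]])
    tilt = spec.tilt_for(label)
    if tilt != 0.0:
        theta = np.deg2rad(tilt)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        centroid = local.mean(axis=0)
        local = (local - centroid) @ rot.T + centroid

    rows, cols = spec.canvas_size
    total = spec.n_vertebrae * h + (spec.n_vertebrae - 1) * spec.gap
    top = max((rows - total) / 2.0, 1.0)
    left = (cols - w) / 2.0
    offset = np.array([top + index * (h + spec.gap), left])
    if subpixel_shift is not None:
        offset = offset + subpixel_shift
    return local + offset


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Render a phantom: pseudo-radiograph, binary mask and exact truth.

    Returns ``(image, mask, truth)`` where ``image`` is float32 in [0, 1],
    ``mask`` is uint8 in {0, 1}, both of shape ``spec.canvas_size``.  The
    mask contains exactly ``spec.n_vertebrae`` 4-connected components
    ordered top to bottom; identical specs (including seed) yield
    bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.canvas_size)
    mask = np.zeros(shape, dtype=np.uint8)

    # generic sub-pixel placement of the whole stack: anatomy never aligns
    # to the pixel grid, and grid-aligned edges are a rasterization
    # knife-edge; a common shift leaves all heights and VCs unchanged
    subpixel_shift = rng.uniform(0.1, 0.9, size=2)

    all_corners = []
    for i in range(spec.n_vertebrae):
        corners = _body_corners(spec, i, subpixel_shift)
        if corners.min() < 0 or corners[:, 0].max() >= shape[0] or corners[:, 1].max() >= shape[1]:
            raise ConfigurationError(
                f"vertebra {i + 1} corners fall outside the canvas")
        rr, cc = draw_polygon(corners[:, 0], corners[:, 1], shape=shape)
        mask[rr, cc] = 1
        all_corners.append(corners)

    heights = [float(np.linalg.norm(c[0] - c[3])) for c in all_corners]
    vertebrae = []
    for i, (corners, ha) in enumerate(zip(all_corners, heights)):
        vc = None
        if 0 < i < spec.n_vertebrae - 1:
            vc = compute_vc(heights[i - 1], ha, heights[i + 1])
        vertebrae.append(VertebraTruth(i + 1, corners, ha, vc))

    image = np.full(shape, _BACKGROUND_INTENSITY, dtype=np.float32)
    image[mask == 1] = _BODY_INTENSITY
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return image, mask, PhantomTruth(vertebrae)


def _sorted_components(mask: np.ndarray):
    labels = cc_label(mask > 0, connectivity=1)
    props = sorted(regionprops(labels), key=lambda p: p.centroid[0])
    return labels, props


def degrade_mask(mask: np.ndarray, mode: str, seed: int = 0) -> np.ndarray:
    """Return a copy of ``mask`` violating exactly one accurate-segmentation
    condition.

    - ``merge_pair``: bridge two vertically adjacent bodies (condition 1);
    - ``erode_corner``: fillet a body's anterior-upper corner into a smooth
      arc so no distinguishable corner remains there (condition 2);
    - ``drop_body``: delete an interior body, breaking adjacency
      (condition 3).
    """
    rng = np.random.default_rng(seed)
    out = (np.asarray(mask) > 0).astype(np.uint8)
    labels, props = _sorted_components(out)
    n = len(props)
    if mode in ("merge_pair", "drop_body") and n < 2:
        raise ValidationError(f"{mode} needs at least 2 components, mask has {n}")
    if n < 1:
        raise ValidationError("mask has no components to degrade")

    if mode == "merge_pair":
        k = int(rng.integers(0, n - 1))
        upper, lower = props[k], props[k + 1]
        c_lo = max(upper.bbox[1], lower.bbox[1])
        c_hi = min(upper.bbox[3], lower.bbox[3])
        col = int(rng.integers(c_lo, max(c_lo + 1, c_hi - 4)))
        out[upper.bbox[0]:lower.bbox[2], col:col + 4] = 1
    elif mode == "erode_corner":
        k = int(rng.integers(0, n))
        r0, c0, r1, c1 = props[k].bbox
        radius = int(0.8 * min(r1 - r0, c1 - c0))
        rr, cc = np.meshgrid(np.arange(r0, r0 + radius), np.arange(c0, c0 + radius),
                             indexing="ij")
        outside = (rr - (r0 + radius)) ** 2 + (cc - (c0 + radius)) ** 2 > radius ** 2
        region = out[r0:r0 + radius, c0:c0 + radius]
        region[outside[:region.shape[0], :region.shape[1]]] = 0
    elif mode == "drop_body":
        k = int(rng.integers(1, n - 1)) if n >= 3 else int(rng.integers(0, n))
        out[labels == props[k].label] = 0
    else:
        raise ValidationError(
            f"unknown degradation mode {mode!r}; expected merge_pair, "
            "erode_corner or drop_body")
    return out


def write_phantom(out_dir, stem: str, image: np.ndarray, mask: np.ndarray,
                  truth: PhantomTruth) -> dict[str, Path]:
    """Write image + mask as 8-bit PNG and truth as CSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}_image.png",
        "mask": out_dir / f"{stem}_mask.png",
        "truth": out_dir / f"{stem}_truth.csv",
    }
    iio.imwrite(paths["image"], (np.clip(image, 0, 1) * 255).astype(np.uint8))
    iio.imwrite(paths["mask"], (mask > 0).astype(np.uint8) * 255)
    truth.to_frame().to_csv(paths["truth"], index=False)
    return paths
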