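"""Division of a segmented spine into three-vertebral-body units.

Connected components of the binary segmentation are labelled top to
bottom (label 1 = topmost).  Before measurement, each mask must pass the
three accurate-segmentation conditions:

1. every vertebral body is segmented as its own component (no merges);
2. four corner vertexes can be found on every body;
3. consecutive bodies are adjacent (no missing body in the stack).

Masks failing any condition are excluded from measurement, mirroring the
clinical-pipeline practice of discarding images that fail to segment.
Passing masks are windowed into sliding triplets (k, k+1, k+2), the unit
on which one compression value is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import CornerDetectionError, ValidationError
from .geometry import _corners_of_coords

__all__ = [
    "VBInstance",
    "VBTriplet",
    "ConditionVerdict",
    "label_components",
    "check_conditions",
    "extract_triplets",
]

#: a component taller than this multiple of the median height indicates a merge
MERGE_HEIGHT_FACTOR = 1.8
#: a vertical gap wider than this multiple of the median height breaks adjacency
ADJACENCY_GAP_FACTOR = 1.0
#: components smaller than this fraction of the median area are speckle
MIN_AREA_FRACTION = 0.01


@dataclass
class VBInstance:
    """One labelled vertebral-body component (label 1 = topmost)."""

    label: int
    coords: np.ndarray            # (n, 2) pixel coordinates (row, col)
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # rmin, cmin, rmax, cmax (exclusive)

    @property
    def height(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def area(self) -> int:
        return self.coords.shape[0]


@dataclass
class VBTriplet:
    """Three vertically adjacent bodies plus their cropped mask raster."""

    upper: VBInstance
    target: VBInstance
    lower: VBInstance
    crop: np.ndarray
    crop_offset: tuple[int, int]
    source_id: str = ""

    @property
    def target_label(self) -> int:
        return self.target.label

    @property
    def component_coords(self) -> list[np.ndarray]:
        """Per-body pixel coordinates relative to the crop, top to bottom."""
        off = np.asarray(self.crop_offset)
        return [inst.coords - off for inst in (self.upper, self.target, self.lower)]


@dataclass
class ConditionVerdict:
    """Outcome of the accurate-segmentation filter for one mask."""

    passed: bool
    condition: int | None = None   # first failed condition id (1, 2 or 3)
    detail: str = ""


def label_components(mask: np.ndarray,
                     min_area_fraction: float = MIN_AREA_FRACTION) -> list[VBInstance]:
    """Label 4-connected foreground components top to bottom.

    Speckle components below ``min_area_fraction`` of the median component
    area are discarded.  An empty mask yields an empty list.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2D, got shape {mask.shape}")
    labels = cc_label(mask > 0, connectivity=1)
    props = regionprops(labels)
    if not props:
        return []
    areas = np.array([p.area for p in props])
    keep = [p for p in props if p.area >= min_area_fraction * np.median(areas)]
    keep.sort(key=lambda p: p.centroid[0])
    return [VBInstance(label=i + 1, coords=np.asarray(p.coords),
                       centroid=tuple(p.centroid), bbox=tuple(p.bbox))
            for i, p in enumerate(keep)]


def check_conditions(instances: list[VBInstance],
                     merge_factor: float = MERGE_HEIGHT_FACTOR,
                     gap_factor: float = ADJACENCY_GAP_FACTOR) -> ConditionVerdict:
    """Apply the three accurate-segmentation conditions; first failure wins."""
    if not instances:
        return ConditionVerdict(False, 1, "no vertebral-body components found")
    heights = np.array([inst.height for inst in instances], dtype=float)
    median_h = float(np.median(heights))

    # condition 1: merged bodies show up as an abnormally tall component
    for inst in instances:
        if inst.height > merge_factor * median_h:
            return ConditionVerdict(
                False, 1,
                f"component {inst.label} height {inst.height} exceeds "
                f"{merge_factor} x median height {median_h:.1f} (merged bodies)")

    # condition 2: every body must expose four corner vertexes
    for inst in instances:
        try:
            _corners_of_coords(inst.coords)
        except CornerDetectionError as exc:
            return ConditionVerdict(
                False, 2, f"component {inst.label}: {exc}")

    # condition 3: consecutive bodies must be adjacent
    for upper, lower in zip(instances, instances[1:]):
        gap = lower.bbox[0] - upper.bbox[2]
        if gap > gap_factor * median_h:
            return ConditionVerdict(
                False, 3,
                f"gap {gap} px between components {upper.label} and "
                f"{lower.label} exceeds {gap_factor} x median height "
                f"{median_h:.1f} (non-adjacent)")

    return ConditionVerdict(True)


def extract_triplets(instances: list[VBInstance], mask: np.ndarray,
                     margin: int = 4, source_id: str = "") -> list[VBTriplet]:
    """Sliding three-body windows (k, k+1, k+2) over the labelled stack.

    Each crop is the joint bounding box of its three components expanded
    by ``margin`` pixels, with all other components zeroed.  Fewer than
    three bodies yield an empty list.
    """
    n = len(instances)
    if n < 3:
        return []
    mask = np.asarray(mask)
    triplets = []
    for k in range(n - 2):
        trio = instances[k:k + 3]
        rmin = max(min(t.bbox[0] for t in trio) - margin, 0)
        cmin = max(min(t.bbox[1] for t in trio) - margin, 0)
        rmax = min(max(t.bbox[2] for t in trio) + margin, mask.shape[0])
        cmax = min(max(t.bbox[3] for t in trio) + margin, mask.shape[1])
        crop = np.zeros((rmax - rmin, cmax - cmin), dtype=np.uint8)
        for t in trio:
            crop[t.coords[:, 0] - rmin, t.coords[:, 1] - cmin] = 1
        shifted = [VBInstance(label=t.label, coords=t.coords,
                              centroid=t.centroid, bbox=t.bbox) for t in trio]
        triplets.append(VBTriplet(upper=shifted[0], target=shifted[1],
                                  lower=shifted[2], crop=crop,
                                  crop_offset=(rmin, cmin), source_id=source_id))
    return triplets
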