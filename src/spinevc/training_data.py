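"""Builders that turn phantom corpora into model-ready training arrays.

Used by the CLI training commands, the test suite and the acceptance
script, so that the scaled-down learning experiments all draw from the
same study conditions: stacks of 4-5 bodies, interior vertebrae
independently compressed with probability 1/2 by a uniform 0-50% anterior
height loss.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .division import check_conditions, extract_triplets, label_components
from .errors import ValidationError
from .phantom import PhantomSpec, PhantomTruth, generate_phantom

__all__ = [
    "small_phantom_spec",
    "random_spec_stream",
    "segmentation_corpus",
    "triplet_crops_from_phantoms",
    "triplet_crops_from_fixtures",
]


def small_phantom_spec(size: int = 128) -> PhantomSpec:
    """A phantom spec whose canvas is a small square grid (for scaled-down
    training runs), with body proportions matching the default spec."""
    h = int(size * 0.19)
    return PhantomSpec(n_vertebrae=4, canvas_size=(size, size), base_height=h,
                       base_width=int(size * 0.55), gap=max(int(size * 0.04), 2))


def random_spec_stream(base: PhantomSpec, rng: np.random.Generator,
                       compression_range: tuple[float, float] = (0.0, 0.5),
                       p_compressed: float = 0.5):
    """Yield endlessly varied phantom specs from ``base``."""
    while True:
        cmap = {}
        for label in range(2, base.n_vertebrae):
            if rng.random() < p_compressed:
                cmap[label] = float(rng.uniform(*compression_range))
        yield replace(base, compression_map=cmap, seed=int(rng.integers(2 ** 31)))


def segmentation_corpus(n: int, seed: int,
                        spec: PhantomSpec | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(images, masks) arrays of ``n`` phantoms for segmentation training."""
    base = spec or small_phantom_spec()
    rng = np.random.default_rng(seed)
    stream = random_spec_stream(base, rng)
    images, masks = [], []
    for _ in range(n):
        image, mask, _ = generate_phantom(next(stream))
        images.append(image)
        masks.append(mask)
    return np.stack(images), np.stack(masks)


def _crops_from_mask(mask: np.ndarray, truth: PhantomTruth,
                     size: tuple[int, int]) -> tuple[list[np.ndarray], list[float]]:
    from .mrdn import prepare_crop

    instances = label_components(mask)
    if not check_conditions(instances).passed:
        return [], []
    crops, targets = [], []
    for trip in extract_triplets(instances, mask):
        true_vc = truth[trip.target_label].true_vc_pct
        if true_vc is None:
            continue
        crops.append(prepare_crop(trip.crop, size))
        targets.append(true_vc)
    return crops, targets


def triplet_crops_from_phantoms(n_phantoms: int, seed: int,
                                spec: PhantomSpec | None = None,
                                size: tuple[int, int] = (128, 128)
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Generate phantoms and return (crops, true VC percents) for all their
    interior vertebrae.  Negative-compression triplets are kept — healthy
    neighbours of collapsed bodies measure negative, and the regressor is
    expected to learn them."""
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    stream = random_spec_stream(base, rng)
    crops, targets = [], []
    for _ in range(n_phantoms):
        _, mask, truth = generate_phantom(next(stream))
        c, t = _crops_from_mask(mask, truth, size)
        crops.extend(c)
        targets.extend(t)
    if not crops:
        raise ValidationError("no measurable triplets produced")
    return np.stack(crops), np.asarray(targets, dtype=np.float32)


def triplet_crops_from_fixtures(fix_dir, size: tuple[int, int] = (128, 128)
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Load a fixture corpus written by ``make_fixtures`` and return
    (crops, true VC percents)."""
    fix_dir = Path(fix_dir)
    crops, targets = [], []
    for mask_path in sorted(fix_dir.glob("*_mask.png")):
        stem = mask_path.name[:-len("_mask.png")]
        mask = iio.imread(mask_path)
        truth = PhantomTruth.from_frame(pd.read_csv(fix_dir / f"{stem}_truth.csv"))
        c, t = _crops_from_mask(mask, truth, size)
        crops.extend(c)
        targets.extend(t)
    if not crops:
        raise ValidationError(f"no measurable triplets found under {fix_dir}")
    return np.stack(crops), np.asarray(targets, dtype=np.float32)
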