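"""Phantom generator: component structure, exact truth, determinism,
degradations."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from spinevc.errors import ConfigurationError, CornerDetectionError, ValidationError
from spinevc.geometry import _corners_of_coords
from spinevc.phantom import (PhantomSpec, PhantomTruth, degrade_mask,
                             generate_phantom, write_phantom)


def test_component_count_matches_spec(default_phantom):
    spec, _, mask, _ = default_phantom
    # independent oracle: scipy 4-connected labelling
    _, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    assert n == spec.n_vertebrae


def test_uncompressed_interior_vc_is_zero(default_phantom):
    _, _, _, truth = default_phantom
    interior = [v for v in truth.vertebrae if v.true_vc_pct is not None]
    assert interior and all(v.true_vc_pct == 0.0 for v in interior)


def test_half_compression_yields_fifty_percent():
    spec = PhantomSpec(n_vertebrae=3, compression_map={2: 0.5}, seed=1)
    _, _, truth = generate_phantom(spec)
    assert truth[2].true_vc_pct == pytest.approx(50.0)


def test_truth_geometry_invariants(default_phantom):
    spec, _, _, truth = default_phantom
    rows, cols = spec.canvas_size
    for v in truth.vertebrae:
        assert (v.corners[:, 0] >= 0).all() and (v.corners[:, 0] < rows).all()
        assert (v.corners[:, 1] >= 0).all() and (v.corners[:, 1] < cols).all()
        assert v.anterior_height == pytest.approx(
            np.linalg.norm(v.corners[0] - v.corners[3]))


def test_seed_determinism():
    spec = PhantomSpec(compression_map={3: 0.2}, seed=99)
    img1, mask1, truth1 = generate_phantom(spec)
    img2, mask2, truth2 = generate_phantom(spec)
    np.testing.assert_array_equal(img1, img2)
    np.testing.assert_array_equal(mask1, mask2)
    for a, b in zip(truth1.vertebrae, truth2.vertebrae):
        np.testing.assert_array_equal(a.corners, b.corners)


def test_different_seeds_differ():
    img1, _, _ = generate_phantom(PhantomSpec(seed=1))
    img2, _, _ = generate_phantom(PhantomSpec(seed=2))
    assert not np.array_equal(img1, img2)


@pytest.mark.parametrize("kwargs, fragment", [
    (dict(n_vertebrae=2), "n_vertebrae"),
    (dict(gap=0), "gap"),
    (dict(n_vertebrae=6, base_height=96), "does not fit"),
    (dict(compression_map={2: 0.7}), "outside [0, 0.6]"),
    (dict(compression_map={9: 0.2}), "label"),
    (dict(noise_sigma=-1), "noise_sigma"),
])
def test_spec_validation_names_constraint(kwargs, fragment):
    import re

    with pytest.raises(ConfigurationError, match=re.escape(fragment)):
        generate_phantom(PhantomSpec(**kwargs))


def test_merge_pair_reduces_component_count(default_phantom):
    spec, _, mask, _ = default_phantom
    merged = degrade_mask(mask, "merge_pair", seed=0)
    _, n = ndimage.label(merged, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    assert n == spec.n_vertebrae - 1


def test_drop_body_removes_interior_component(default_phantom):
    spec, _, mask, _ = default_phantom
    dropped = degrade_mask(mask, "drop_body", seed=0)
    _, n = ndimage.label(dropped, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    assert n == spec.n_vertebrae - 1


def test_erode_corner_destroys_a_corner(default_phantom):
    _, _, mask, truth = default_phantom
    eroded = degrade_mask(mask, "erode_corner", seed=3)
    labels, n = ndimage.label(eroded,
                              structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    failures = 0
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        try:
            _corners_of_coords(coords)
        except CornerDetectionError:
            failures += 1
    assert failures == 1


def test_degrade_requires_enough_components():
    tiny = np.zeros((32, 32), dtype=np.uint8)
    tiny[4:12, 4:12] = 1
    with pytest.raises(ValidationError):
        degrade_mask(tiny, "merge_pair")
    with pytest.raises(ValidationError):
        degrade_mask(np.zeros((8, 8), dtype=np.uint8), "erode_corner")


def test_unknown_degrade_mode(default_phantom):
    _, _, mask, _ = default_phantom
    with pytest.raises(ValidationError, match="unknown degradation mode"):
        degrade_mask(mask, "blur")


def test_write_phantom_roundtrip(tmp_path, default_phantom):
    import imageio.v3 as iio

    _, image, mask, truth = default_phantom
    paths = write_phantom(tmp_path, "p0", image, mask, truth)
    mask_back = iio.imread(paths["mask"])
    np.testing.assert_array_equal(mask_back > 0, mask > 0)
    truth_back = PhantomTruth.from_frame(pd.read_csv(paths["truth"]))
    for a, b in zip(truth.vertebrae, truth_back.vertebrae):
        assert a.label == b.label
        np.testing.assert_allclose(a.corners, b.corners)
        if a.true_vc_pct is None:
            assert b.true_vc_pct is None
        else:
            assert b.true_vc_pct == pytest.approx(a.true_vc_pct)


def test_spec_from_yaml(tmp_path):
    path = tmp_path / "spec.yaml"
    path.write_text(
        "n_vertebrae: 3\ncanvas_size: [256, 256]\nbase_height: 48\n"
        "base_width: 60\ngap: 6\ncompression_map:\n  2: 0.25\nseed: 5\n")
    spec = PhantomSpec.from_yaml(path)
    assert spec.canvas_size == (256, 256)
    assert spec.compression_map == {2: 0.25}
    _, _, truth = generate_phantom(spec)
    assert truth[2].true_vc_pct == pytest.approx(25.0, abs=1e-9)
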