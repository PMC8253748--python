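"""Corner detection, left/right partition, anterior heights and the
compression formula."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinevc.division import extract_triplets, label_components
from spinevc.errors import ComputationError, CornerDetectionError, PartitionError
from spinevc.geometry import (VertexSet, _corners_of_coords, anterior_heights,
                              compute_vc, detect_vertexes, measure_triplet,
                              render_overlay, split_left_right)
from spinevc.phantom import PhantomSpec, generate_phantom


def _rect_coords(r0, c0, h, w):
    rr, cc = np.meshgrid(np.arange(r0, r0 + h), np.arange(c0, c0 + w),
                         indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


class TestCornerDetection:
    def test_rectangle_corners_exact(self):
        coords = _rect_coords(10, 20, 30, 40)
        vs = _corners_of_coords(coords, refine=False)
        expected = np.array([[10, 20], [10, 59], [39, 59], [39, 20]])
        np.testing.assert_allclose(vs.corners, expected)

    def test_disk_has_no_corners(self):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        coords = np.argwhere((rr - 32) ** 2 + (cc - 32) ** 2 <= 500)
        with pytest.raises(CornerDetectionError):
            _corners_of_coords(coords)

    def test_tiny_component_rejected(self):
        with pytest.raises(CornerDetectionError, match="too small"):
            _corners_of_coords(_rect_coords(0, 0, 3, 3))

    def test_phantom_corners_within_2px(self, default_phantom):
        _, _, mask, truth = default_phantom
        for inst in label_components(mask):
            vs = _corners_of_coords(inst.coords)
            err = np.abs(vs.corners - truth[inst.label].corners).max()
            assert err <= 2.0


class TestSplitLeftRight:
    def test_vertical_line_splits_by_column(self):
        vsets = [VertexSet(corners=np.array([[0., 0.], [0., 10.], [10., 10.], [10., 0.]]) + [i * 20, 0],
                           center=np.array([5.0 + i * 20, 5.0]))
                 for i in range(3)]
        out = split_left_right(vsets)
        for vs in out:
            assert (vs.left[:, 1] == 0).all()
            assert (vs.right[:, 1] == 10).all()
            assert vs.left[0, 0] < vs.left[1, 0]

    def test_tilted_phantom_left_pair_matches_truth(self):
        spec = PhantomSpec(compression_map={2: 0.3}, tilt_deg=10, seed=3)
        _, mask, truth = generate_phantom(spec)
        trip = extract_triplets(label_components(mask), mask)[0]
        vsets = split_left_right(detect_vertexes(trip))
        off = np.asarray(trip.crop_offset)
        for vs, inst in zip(vsets, (trip.upper, trip.target, trip.lower)):
            true_left = truth[inst.label].left_pair - off
            np.testing.assert_allclose(vs.left, true_left, atol=2.0)

    def test_coincident_centers_error(self):
        vs = VertexSet(corners=np.zeros((4, 2)), center=np.array([1.0, 1.0]))
        with pytest.raises(PartitionError):
            split_left_right([vs, VertexSet(corners=np.zeros((4, 2)),
                                            center=np.array([1.0, 1.0]))])

    def test_all_vertexes_one_side_error(self):
        bodies = [VertexSet(corners=np.array([[0., 5.], [0., 9.], [4., 9.], [4., 5.]]) + [i * 10, 0],
                            center=np.array([2.0 + i * 10, 0.0]))
                  for i in range(3)]
        with pytest.raises(PartitionError, match="malformed"):
            split_left_right(bodies)


class TestHeightsAndVC:
    def test_height_is_distance_between_left_points(self):
        vsets = []
        for i in range(3):
            vs = VertexSet(corners=np.zeros((4, 2)), center=np.zeros(2))
            vs.left = np.array([[10.0 + 40 * i, 5.0], [30.0 + 40 * i, 5.0]])
            vs.right = vs.left + [0, 20]
            vsets.append(vs)
        assert anterior_heights(vsets) == (20.0, 20.0, 20.0)

    def test_unpartitioned_raises(self):
        vs = VertexSet(corners=np.zeros((4, 2)), center=np.zeros(2))
        with pytest.raises(PartitionError):
            anterior_heights([vs, vs, vs])

    @pytest.mark.parametrize("heights, expected", [
        ((20, 10, 20), 50.0),
        ((7, 7, 7), 0.0),
        ((10, 12, 10), -20.0),
    ])
    def test_compute_vc_examples(self, heights, expected):
        assert compute_vc(*heights) == pytest.approx(expected)

    def test_compute_vc_max_denominator(self):
        assert compute_vc(20, 10, 30, denominator="max") == pytest.approx(
            (30 - 10) / 30 * 100)

    def test_compute_vc_rejects_nonpositive_neighbors(self):
        with pytest.raises(ComputationError):
            compute_vc(0, 10, 20)
        with pytest.raises(ComputationError):
            compute_vc(20, 10, -1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hu=st.floats(1, 200), ht=st.floats(0.1, 200), hl=st.floats(1, 200),
           c=st.floats(0.01, 100))
    def test_compute_vc_scale_invariant_and_bounded(self, hu, ht, hl, c):
        vc = compute_vc(hu, ht, hl)
        assert vc <= 100
        assert compute_vc(c * hu, c * ht, c * hl) == pytest.approx(vc, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hu=st.floats(1, 200), hl=st.floats(1, 200),
           ht=st.floats(0.1, 100), delta=st.floats(0.1, 50))
    def test_compute_vc_decreasing_in_target(self, hu, hl, ht, delta):
        assert compute_vc(hu, ht + delta, hl) < compute_vc(hu, ht, hl)


def test_measure_triplet_matches_truth(compressed_phantom):
    _, _, mask, truth = compressed_phantom
    for trip in extract_triplets(label_components(mask), mask):
        m = trip.target_label, measure_triplet(trip)
        assert m[1].vc_pct == pytest.approx(truth[m[0]].true_vc_pct, abs=1.5)
        assert m[1].method == "geometry"


def test_render_overlay_paints_markers(compressed_phantom):
    _, _, mask, _ = compressed_phantom
    trip = extract_triplets(label_components(mask), mask)[0]
    vsets = split_left_right(detect_vertexes(trip))
    rgb = render_overlay(trip.crop, vsets)
    assert rgb.shape == trip.crop.shape + (3,)
    # green centres and yellow left markers present
    assert (rgb == [0, 255, 0]).all(axis=-1).any()
    assert (rgb == [255, 255, 0]).all(axis=-1).any()
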