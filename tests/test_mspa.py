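import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from morphoscape.mspa import (
    MspaParams,
    classify_boundary,
    classify_connectors,
    eroded_core,
    find_holes,
    segment,
)
from morphoscape.nomenclature import MSPA_CODES, STRUCTURE_NAMES

from oracle import segment_oracle


def embed(block, shape, offset=(0, 0)):
    out = np.zeros(shape, dtype=bool)
    block = np.asarray(block, dtype=bool)
    out[offset[0]: offset[0] + block.shape[0], offset[1]: offset[1] + block.shape[1]] = block
    return out


def assert_matches_oracle(mask, edge_width=1, border_condition="background"):
    seg = segment(mask, MspaParams(edge_width=edge_width, border_condition=border_condition))
    expected = segment_oracle(mask.tolist(), edge_width, border_condition)
    for name in STRUCTURE_NAMES:
        got = set(zip(*np.nonzero(seg.types == MSPA_CODES[name])))
        got = {(int(i), int(j)) for i, j in got}
        assert got == expected[name], f"{name} differs\n{mask.astype(int)}"


class TestErodedCore:
    def test_3x3_square_leaves_centre(self):
        mask = embed(np.ones((3, 3)), (5, 5), (1, 1))
        core = eroded_core(mask, 1).values
        assert core.sum() == 1 and core[2, 2]

    def test_2x2_square_has_no_interior(self):
        mask = embed(np.ones((2, 2)), (4, 4), (1, 1))
        assert not eroded_core(mask, 1).values.any()

    def test_all_foreground_border_as_background(self):
        mask = np.ones((6, 6), dtype=bool)
        core = eroded_core(mask, 1).values
        assert core.sum() == 16  # (n-2)^2 interior
        assert core[1:-1, 1:-1].all()

    def test_all_foreground_border_as_foreground(self):
        mask = np.ones((6, 6), dtype=bool)
        assert eroded_core(mask, 1, border_condition="foreground").values.all()

    def test_matches_distance_transform_oracle(self, rng):
        from oracle import _border_distance, _cheb

        mask = rng.uniform(size=(10, 10)) < 0.7
        bg = [(i, j) for i in range(10) for j in range(10) if not mask[i, j]]
        for w in (1, 2):
            core = eroded_core(mask, w).values
            for i in range(10):
                for j in range(10):
                    if not mask[i, j]:
                        continue
                    d = min(
                        min((_cheb((i, j), b) for b in bg), default=np.inf),
                        _border_distance((i, j), 10, 10),
                    )
                    assert core[i, j] == (d > w)


class TestFindHoles:
    def test_solid_square_has_no_holes(self):
        assert find_holes(embed(np.ones((4, 4)), (6, 6), (1, 1))).n_labels == 0

    def test_single_pixel_hole(self):
        ring = np.ones((3, 3), dtype=bool)
        ring[1, 1] = False
        holes = find_holes(embed(ring, (5, 5), (1, 1)))
        assert holes.n_labels == 1
        assert (holes.values > 0).sum() == 1

    def test_two_donuts_two_holes(self):
        donut = np.ones((3, 3), dtype=bool)
        donut[1, 1] = False
        mask = embed(donut, (5, 9), (1, 1)) | embed(donut, (5, 9), (1, 5))
        assert find_holes(mask).n_labels == 2

    def test_border_touching_background_is_not_a_hole(self):
        # C-shape: concavity open to the border
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 1:] = False
        assert find_holes(embed(mask, (5, 5), (1, 1))).n_labels == 0


class TestClassifyBoundary:
    def test_square_boundary_all_edge(self):
        mask = embed(np.ones((5, 5)), (9, 9), (2, 2))
        core = eroded_core(mask, 1).values
        edge, perf = classify_boundary(mask, core, find_holes(mask), 1)
        assert edge.sum() == 16 and perf.sum() == 0

    def test_thick_ring_inner_rim_perforation(self):
        ring = np.ones((7, 7), dtype=bool)
        ring[3, 3] = False
        mask = embed(ring, (11, 11), (2, 2))
        core = eroded_core(mask, 1).values
        edge, perf = classify_boundary(mask, core, find_holes(mask), 1)
        # inner rim = 8 pixels around the hole
        assert perf.sum() == 8
        assert edge.sum() == 24  # outer rim of the 7x7 ring

    def test_no_core_means_empty_boundary(self):
        mask = embed(np.ones((2, 2)), (5, 5), (1, 1))
        core = eroded_core(mask, 1).values
        edge, perf = classify_boundary(mask, core, find_holes(mask), 1)
        assert not edge.any() and not perf.any()


class TestConnectors:
    def test_isolated_blob_is_islet(self):
        mask = embed(np.ones((2, 2)), (8, 8), (5, 5))
        seg = segment(mask)
        assert seg.pixel_counts()["islet"] == 4

    def test_path_from_core_is_branch(self):
        mask = np.zeros((7, 9), dtype=bool)
        mask[1:6, 1:6] = True  # 5x5 square: core + edge
        mask[3, 6:8] = True  # 2-px tail into background
        seg = segment(mask)
        counts = seg.pixel_counts()
        assert counts["branch"] == 2
        assert counts["core"] == 9 and counts["edge"] == 16

    def test_u_path_reentering_same_core_is_loop(self):
        mask = np.zeros((9, 11), dtype=bool)
        mask[1:6, 1:6] = True  # square with one core
        # U-shaped corridor leaving the top row and re-entering the bottom
        # row, far enough apart that the two contact regions stay disjoint
        mask[1, 6:9] = True
        mask[2:5, 8] = True
        mask[5, 6:9] = True
        seg = segment(mask)
        counts = seg.pixel_counts()
        assert counts["loop"] == 9
        assert counts["bridge"] == 0 and counts["branch"] == 0

    def test_path_joining_two_cores_is_bridge(self):
        mask = np.zeros((7, 13), dtype=bool)
        mask[2:5, 1:4] = True
        mask[2:5, 7:10] = True
        mask[3, 4:7] = True
        counts = segment(mask).pixel_counts()
        assert counts["bridge"] == 3
        assert counts["core"] == 2

    def test_islet_components_touch_no_core(self, rng):
        mask = rng.uniform(size=(20, 20)) < 0.45
        seg = segment(mask)
        islet = seg.mask_of("islet")
        core = seg.mask_of("core")
        from scipy import ndimage

        near_core = ndimage.binary_dilation(core, structure=np.ones((3, 3), dtype=bool))
        assert not (islet & near_core).any()


class TestSegmentContract:
    def test_empty_mask_all_none(self):
        seg = segment(np.zeros((4, 4), dtype=bool))
        assert (seg.types == 0).all()

    def test_all_foreground_is_all_core_with_open_border(self):
        seg = segment(np.ones((5, 5), dtype=bool), MspaParams(border_condition="foreground"))
        assert (seg.types == MSPA_CODES["core"]).all()

    def test_centre_hole_square_is_all_islet(self):
        block = np.ones((5, 5), dtype=bool)
        block[2, 2] = False
        seg = segment(embed(block, (7, 7), (1, 1)))
        assert seg.pixel_counts()["islet"] == 24

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        arrays(bool, (7, 7), elements=st.booleans()),
        st.integers(min_value=1, max_value=3),
    )
    def test_partition_invariant(self, mask, edge_width):
        seg = segment(mask, MspaParams(edge_width=edge_width))
        assert sum(seg.pixel_counts().values()) == int(mask.sum())

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(arrays(bool, (8, 8), elements=st.booleans()))
    def test_core_monotone_in_edge_width(self, mask):
        c1 = segment(mask, MspaParams(edge_width=1)).pixel_counts()["core"]
        c2 = segment(mask, MspaParams(edge_width=2)).pixel_counts()["core"]
        assert c2 <= c1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(arrays(bool, (8, 8), elements=st.booleans()))
    def test_mirror_equivariance(self, mask):
        seg = segment(mask).types
        seg_h = segment(mask[:, ::-1]).types
        seg_v = segment(mask[::-1, :]).types
        np.testing.assert_array_equal(seg[:, ::-1], seg_h)
        np.testing.assert_array_equal(seg[::-1, :], seg_v)


class TestOracleEquivalence:
    def test_exhaustive_3x3(self):
        for bits in range(512):
            mask = np.array([(bits >> k) & 1 for k in range(9)], dtype=bool).reshape(3, 3)
            assert_matches_oracle(mask)

    def test_random_4x4_to_6x6(self, rng):
        for shape in ((4, 4), (5, 5), (6, 6)):
            for _ in range(150):
                mask = rng.uniform(size=shape) < rng.uniform(0.2, 0.9)
                assert_matches_oracle(mask)

    def test_random_larger_edge_width(self, rng):
        for _ in range(60):
            mask = rng.uniform(size=(8, 8)) < 0.7
            assert_matches_oracle(mask, edge_width=2)

    def test_foreground_border_condition(self, rng):
        for _ in range(60):
            mask = rng.uniform(size=(6, 6)) < 0.7
            assert_matches_oracle(mask, border_condition="foreground")
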