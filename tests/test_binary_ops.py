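"""Unit and property tests for the binary image primitives, checked
bit-exactly against independent brute-force oracles."""

import numpy as np
import pytest

from woundmetry import binary_ops as bo
from woundmetry.errors import DegenerateHistogramError, InvalidInputError

from _oracles import (
    clear_border_flood,
    dilate_loop,
    erode_loop,
    fill_holes_flood,
    grayscale_loop,
    label_flood,
    otsu_exhaustive,
)
from conftest import random_masks

SE3 = bo.square_se(3)


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((255, 0, 0), 76)],
    )
    def test_known_pixels(self, rgb, expected):
        img = np.full((1, 1, 3), rgb, dtype=np.uint8)
        assert bo.to_grayscale(img)[0, 0] == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(7, 9, 3), dtype=np.uint8)
        np.testing.assert_array_equal(bo.to_grayscale(img), grayscale_loop(img))

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            bo.to_grayscale(np.zeros((0, 3, 3), dtype=np.uint8))


class TestOtsu:
    def test_two_level_image_smallest_threshold(self):
        img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        assert bo.otsu_threshold(img) == otsu_exhaustive(img) == 0

    def test_four_pixel_histogram_separates_classes(self):
        img = np.array([[10, 10], [10, 200]], dtype=np.uint8)
        t = bo.otsu_threshold(img)
        assert 10 <= t < 200  # the {10} pixels and the {200} pixel split
        assert t == otsu_exhaustive(img)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        assert bo.otsu_threshold(img) == otsu_exhaustive(img)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            bo.otsu_threshold(np.full((4, 4), 7, dtype=np.uint8))


class TestBinarizeInverted:
    def test_dark_becomes_foreground(self):
        assert bo.binarize_inverted(np.zeros((3, 3), dtype=np.uint8), 128).all()
        assert not bo.binarize_inverted(np.full((3, 3), 255, np.uint8), 128).any()

    def test_checkerboard_complement(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 * 255
        np.testing.assert_array_equal(bo.binarize_inverted(img, 127), 1 - img // 255)


class TestMorphology:
    def test_dilate_point_gives_se_footprint(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        assert bo.dilate(m, SE3).sum() == 9
        assert bo.dilate(m, SE3)[1:4, 1:4].all()

    def test_erode_block_gives_center(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:4, 1:4] = 1
        out = bo.erode(m, SE3)
        assert out.sum() == 1 and out[2, 2] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_dilate_erode_match_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((9, 9)) < 0.5).astype(np.uint8)
        np.testing.assert_array_equal(bo.dilate(m, SE3), dilate_loop(m, SE3))
        np.testing.assert_array_equal(bo.erode(m, SE3), erode_loop(m, SE3))
        np.testing.assert_array_equal(
            bo.erode(bo.dilate(m, SE3), SE3), erode_loop(dilate_loop(m, SE3), SE3)
        )

    def test_close_bridges_nearby_pixels(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[3, 2] = m[3, 4] = 1
        closed = bo.close(m, SE3)
        assert bo.label_components(closed).n_components == 1

    def test_open_removes_specks_keeps_blocks(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[1, 1] = 1  # isolated speck
        m[3:8, 3:8] = 1  # 5x5 block
        out = bo.open_(m, SE3)
        assert out[1, 1] == 0
        np.testing.assert_array_equal(out[3:8, 3:8], 1)
        assert out.sum() == 25

    @pytest.mark.parametrize("seed", range(8))
    def test_idempotence_and_extensivity(self, seed):
        (m,) = random_masks(1, seed + 300)
        closed = bo.close(m, SE3)
        opened = bo.open_(m, SE3)
        np.testing.assert_array_equal(bo.close(closed, SE3), closed)
        np.testing.assert_array_equal(bo.open_(opened, SE3), opened)
        assert (closed >= m).all()  # closing never shrinks
        assert (opened <= m).all()  # opening never grows

    def test_empty_se_rejected(self):
        with pytest.raises(InvalidInputError):
            bo.dilate(np.ones((3, 3), dtype=np.uint8), np.zeros((3, 3), dtype=bool))


class TestFillHoles:
    def test_ring_fills(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:4, 1:4] = 1
        m[2, 2] = 0
        out = bo.fill_holes(m)
        np.testing.assert_array_equal(out, fill_holes_flood(m))
        assert out[2, 2] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_flood_oracle_and_idempotent(self, seed):
        (m,) = random_masks(1, seed + 600)
        out = bo.fill_holes(m)
        np.testing.assert_array_equal(out, fill_holes_flood(m))
        np.testing.assert_array_equal(bo.fill_holes(out), out)

    def test_no_enclosed_background_unchanged(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[0:2, 0:2] = 1
        np.testing.assert_array_equal(bo.fill_holes(m), m)
        z = np.zeros((3, 3), dtype=np.uint8)
        np.testing.assert_array_equal(bo.fill_holes(z), z)


class TestComponents:
    def test_two_blocks(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[0:2, 0:2] = 1
        m[4:6, 4:6] = 1
        assert bo.label_components(m).n_components == 2

    def test_diagonal_connectivity(self):
        m = np.eye(3, dtype=np.uint8)
        assert bo.label_components(m, 8).n_components == 1
        assert bo.label_components(m, 4).n_components == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        (m,) = random_masks(1, seed + 900)
        got = bo.label_components(m, connectivity)
        want_labels, want_n = label_flood(m, connectivity)
        assert got.n_components == want_n
        np.testing.assert_array_equal(got.labels, want_labels)


class TestClearBorder:
    def test_interior_survives(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[0, 2:4] = 1  # touches top
        m[3:5, 3:5] = 1  # interior
        out = bo.clear_border_objects(bo.label_components(m))
        assert out[0].sum() == 0 and out[3:5, 3:5].all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_border_flood_oracle(self, seed):
        (m,) = random_masks(1, seed + 1200)
        out = bo.clear_border_objects(bo.label_components(m))
        np.testing.assert_array_equal(out, clear_border_flood(m))
        # anti-extensive, border-free, idempotent
        assert (out <= m).all()
        assert not (out[0].any() or out[-1].any() or out[:, 0].any() or out[:, -1].any())
        np.testing.assert_array_equal(
            bo.clear_border_objects(bo.label_components(out)), out
        )


class TestAreaFilter:
    def test_range_selects_by_area(self):
        m = np.zeros((40, 40), dtype=np.uint8)
        m[1, 1:6] = 1
        m[5:10, 10:20] = 1
        m[15:35, 15:40] = 1
        lab = bo.label_components(m)
        out = bo.area_filter(lab, 40, 100)
        assert bo.count_foreground(out) == 50

    def test_unbounded_range_is_identity(self):
        (m,) = random_masks(1, 2024)
        lab = bo.label_components(m)
        np.testing.assert_array_equal(bo.area_filter(lab, 0, np.inf), m)

    def test_bounds_inclusive(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:3, 1:3] = 1  # area exactly 4
        lab = bo.label_components(m)
        assert bo.count_foreground(bo.area_filter(lab, 4, 4)) == 4

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation(self, seed):
        (m,) = random_masks(1, seed + 1500)
        lab = bo.label_components(m)
        stats = bo.component_stats(lab)
        lo, hi = 3, 12
        kept = bo.area_filter(lab, lo, hi)
        expected = sum(s.pixel_area for s in stats if lo <= s.pixel_area <= hi)
        assert bo.count_foreground(kept) == expected


class TestCount:
    def test_extremes(self):
        assert bo.count_foreground(np.zeros((10, 10), dtype=np.uint8)) == 0
        assert bo.count_foreground(np.ones((10, 10), dtype=np.uint8)) == 100

    def test_matches_double_loop(self):
        (m,) = random_masks(1, 7)
        assert bo.count_foreground(m) == sum(
            int(m[r, c]) for r in range(m.shape[0]) for c in range(m.shape[1])
        )


class TestComponentStats:
    def test_geometry_invariants(self):
        (m,) = random_masks(1, 11)
        for s in bo.component_stats(bo.label_components(m)):
            r0, c0, r1, c1 = s.bbox
            assert 1 <= s.pixel_area <= (r1 - r0) * (c1 - c0)
            assert 0 < s.extent <= 1
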