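"""Orientation field, singular points, skeleton and minutiae extraction."""

import numpy as np
import pytest
import skimage.draw as draw
from skimage.measure import label as cc_label

import lfpmatch as lm
from lfpmatch.errors import (
    ConfigurationError,
    DegenerateImageError,
    NoFeaturesError,
    PreconditionError,
)
from lfpmatch.imgproc import BinaryImage, GrayImage
from lfpmatch.ridges import CompoundParams, _cn_map, poincare_index


def stripes(angle="horizontal", size=64, period=8):
    y, x = np.mgrid[0:size, 0:size]
    coord = y if angle == "horizontal" else x
    return GrayImage(128 + 100 * np.sin(2 * np.pi * coord / period), stage="raw")


class TestOrientation:
    def test_horizontal_stripes_give_theta_zero(self):
        fld = lm.estimate_orientation(stripes("horizontal"), 16)
        dev = np.minimum(fld.theta, np.pi - fld.theta)  # distance to 0 mod pi
        assert dev.max() < 0.05
        assert fld.coherence.mean() > 0.95

    def test_vertical_stripes_give_theta_half_pi(self):
        fld = lm.estimate_orientation(stripes("vertical"), 16)
        assert np.abs(fld.theta - np.pi / 2).max() < 0.05

    def test_noise_less_coherent_than_stripes(self):
        coh_stripes = lm.estimate_orientation(stripes(), 16).coherence.mean()
        noise_coh = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = GrayImage(rng.uniform(0, 255, (64, 64)), stage="raw")
            noise_coh.append(lm.estimate_orientation(img, 16).coherence.mean())
        assert np.mean(noise_coh) < coh_stripes

    def test_block_larger_than_image_rejected(self):
        with pytest.raises(ConfigurationError):
            lm.estimate_orientation(stripes(size=32), 64)


class TestDetectCore:
    def test_uniform_field_has_no_singularity(self):
        fld = lm.OrientationField(np.full((12, 12), 0.7), 16, np.ones((12, 12)))
        assert lm.detect_core(fld) == []

    def test_whorl_field_gives_plus_one_core_near_center(self):
        fld = lm.make_orientation_field("whorl", core=(128, 128), size=256, block_size=16)
        pts = lm.detect_core(fld)
        assert pts and pts[0].kind == "core" and pts[0].poincare_index == 1.0
        assert np.hypot(pts[0].a - 128, pts[0].b - 128) <= 16

    def test_loop_field_gives_half_core_and_delta(self):
        fld = lm.make_orientation_field("loop", size=256, block_size=16)
        pts = lm.detect_core(fld)
        kinds = {(p.kind, p.poincare_index) for p in pts}
        assert ("core", 0.5) in kinds and ("delta", -0.5) in kinds

    def test_indices_sum_to_half_integers(self, whorl_field):
        fld = lm.make_orientation_field("loop", size=128, block_size=8)
        idx = poincare_index(fld)
        total = idx.sum()
        assert abs(total * 2 - round(total * 2)) < 0.05


class TestSkeletonize:
    def test_wide_bar_thins_to_centerline(self):
        p = np.zeros((30, 60), np.uint8)
        p[13:18, 5:55] = 1
        skel = lm.skeletonize(BinaryImage(p))
        ys, xs = np.nonzero(skel.pixels)
        assert np.all(np.abs(ys - 15) <= 1)
        assert xs.min() <= 7 and xs.max() >= 53
        # one pixel wide: each column has exactly one skeleton pixel
        counts = np.bincount(xs)
        assert counts[counts > 0].max() == 1

    def test_single_pixel_is_fixed_point(self):
        p = np.zeros((10, 10), np.uint8)
        p[5, 5] = 1
        assert np.array_equal(lm.skeletonize(BinaryImage(p)).pixels, p)

    def test_skeleton_subset_of_mask_and_components_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = np.zeros((48, 48), np.uint8)
            for _ in range(rng.integers(1, 5)):
                y, x = rng.integers(6, 42, 2)
                rr, cc = draw.disk((y, x), rng.integers(3, 6), shape=p.shape)
                p[rr, cc] = 1
            skel = lm.skeletonize(BinaryImage(p))
            assert np.all(p[skel.pixels == 1] == 1)
            assert (
                cc_label(skel.pixels, connectivity=2).max()
                == cc_label(p, connectivity=2).max()
            )

    def test_empty_foreground_raises(self):
        with pytest.raises(DegenerateImageError):
            lm.skeletonize(BinaryImage(np.zeros((16, 16), np.uint8)))


def brute_force_cn(ring):
    return sum(abs(ring[k] - ring[(k + 1) % 8]) for k in range(8)) // 2


class TestCrossingNumber:
    def test_isolated_pixel_is_zero(self):
        p = np.zeros((9, 9), np.uint8)
        p[4, 4] = 1
        assert lm.crossing_number(BinaryImage(p), 4, 4) == 0

    def test_line_interior_is_two_and_cross_center_is_four(self):
        p = np.zeros((9, 9), np.uint8)
        p[4, :] = 1
        assert lm.crossing_number(BinaryImage(p), 4, 4) == 2
        p[:, 4] = 1
        assert lm.crossing_number(BinaryImage(p), 4, 4) == 4

    def test_off_skeleton_pixel_rejected(self):
        p = np.zeros((9, 9), np.uint8)
        p[4, 4] = 1
        with pytest.raises(PreconditionError):
            lm.crossing_number(BinaryImage(p), 1, 1)

    def test_all_256_neighborhoods_match_brute_force(self):
        # ring order used by the implementation: E, NE, N, NW, W, SW, S, SE
        offs = [(1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1)]
        for bits in range(256):
            ring = [(bits >> k) & 1 for k in range(8)]
            p = np.zeros((5, 5), np.uint8)
            p[2, 2] = 1
            for (dx, dy), v in zip(offs, ring):
                p[2 + dy, 2 + dx] = v
            assert lm.crossing_number(BinaryImage(p), 2, 2) == brute_force_cn(ring)
            # vectorized map agrees with the scalar operator
            assert _cn_map(p)[2, 2] == brute_force_cn(ring)


class TestExtractMinutiae:
    def test_straight_segment_has_two_terminations(self):
        p = np.zeros((12, 20), np.uint8)
        p[6, 5:15] = 1
        ms = lm.extract_minutiae(BinaryImage(p))
        assert len(ms.of_type("termination")) == 2
        assert len(ms.of_type("bifurcation")) == 0

    def test_y_shape_has_one_bifurcation_three_terminations(self):
        p = np.zeros((40, 40), np.uint8)
        p[20, 4:20] = 1
        for k in range(1, 14):
            p[20 - k, 19 + k] = 1
            p[20 + k, 19 + k] = 1
        ms = lm.extract_minutiae(BinaryImage(p))
        assert len(ms.of_type("bifurcation")) == 1
        assert len(ms.of_type("termination")) == 3

    def test_empty_skeleton_raises(self):
        with pytest.raises(NoFeaturesError):
            lm.extract_minutiae(BinaryImage(np.zeros((10, 10), np.uint8)))

    @pytest.mark.parametrize("dx,dy", [(3, 0), (0, 4), (5, 7)])
    def test_translation_equivariance(self, dx, dy):
        p = np.zeros((40, 40), np.uint8)
        p[10, 5:20] = 1
        for k in range(1, 8):
            p[10 + k, 19 + k] = 1
            p[10 - k, 19 + k] = 1
        shifted = np.roll(np.roll(p, dy, axis=0), dx, axis=1)
        ms0 = lm.extract_minutiae(BinaryImage(p))
        ms1 = lm.extract_minutiae(BinaryImage(shifted))
        c0 = ms0.coords() + (dx, dy)
        np.testing.assert_array_equal(np.sort(c0, axis=0), np.sort(ms1.coords(), axis=0))


class TestCompound:
    def test_short_ring_on_ridge_becomes_eye(self):
        p = np.zeros((40, 60), np.uint8)
        rr, cc = draw.circle_perimeter(20, 30, 4)  # circumference ~ 20 px
        p[rr, cc] = 1
        p[20, 5:27] = 1
        p[20, 34:55] = 1
        skel = BinaryImage(p)
        ms = lm.classify_compound(lm.extract_minutiae(skel), skel, CompoundParams(l_eye=30))
        assert len(ms.of_type("eye")) == 1
        assert len(ms.of_type("bifurcation")) == 0

    def test_short_branch_becomes_spur_and_consumes_tip(self):
        p = np.zeros((40, 60), np.uint8)
        p[20, 5:55] = 1
        for k in range(1, 5):  # 4 px branch
            p[20 - k, 30 + k] = 1
        skel = BinaryImage(p)
        ms = lm.classify_compound(
            lm.extract_minutiae(skel), skel, CompoundParams(l_spur=8, l_prune=0)
        )
        assert len(ms.of_type("spur")) == 1
        assert len(ms.of_type("termination")) == 2  # only the two line ends

    def test_plain_bifurcation_with_long_arms_unchanged(self):
        p = np.zeros((60, 60), np.uint8)
        p[30, 5:30] = 1
        for k in range(1, 25):
            p[30 - k // 2, 29 + k] = 1
            p[30 + k // 2, 29 + k] = 1
        skel = BinaryImage(p)
        before = lm.extract_minutiae(skel)
        after = lm.classify_compound(before, skel)
        assert len(after.of_type("bifurcation")) == 1
        assert len(after.of_type("termination")) == 3

    def test_isolated_ring_is_lake_and_free_segment_is_short_ridge(self):
        p = np.zeros((40, 60), np.uint8)
        rr, cc = draw.circle_perimeter(20, 15, 4)
        p[rr, cc] = 1
        p[10, 35:45] = 1
        skel = BinaryImage(p)
        ms = lm.classify_compound(lm.extract_minutiae(skel), skel)
        assert len(ms.of_type("lake")) == 1
        assert len(ms.of_type("short_ridge")) == 1


class TestPores:
    def _bar_with_hole(self, hole_radius):
        p = np.ones((40, 60), np.uint8)
        p[:5] = p[-5:] = 0  # background stripes touch the border
        rr, cc = draw.disk((20, 30), hole_radius, shape=p.shape)
        p[rr, cc] = 0
        return BinaryImage(p)

    def test_small_enclosed_hole_is_pore(self):
        ms = lm.detect_pores(None, self._bar_with_hole(1.6))
        assert len(ms.of_type("pore")) == 1

    def test_oversized_hole_rejected(self):
        ms = lm.detect_pores(None, self._bar_with_hole(4.0))  # area ~ 50 px
        assert len(ms.of_type("pore")) == 0

    def test_planted_pores_recovered(self, whorl_field):
        gray, mask = lm.render_ridge_image(
            whorl_field, 9.0, seed=3, pattern="whorl", core=(128, 128)
        )
        g2, m2, truth = lm.plant_minutiae(
            gray, mask, whorl_field, 5, types=("pore",), seed=3, keepout=[(128, 128)]
        )
        ms = lm.detect_pores(g2, m2)
        n_true = len(truth.of_type("pore"))
        assert n_true == 5
        hits = 0
        P = ms.coords()
        for t in truth:
            if len(P) and np.hypot(P[:, 0] - t.x, P[:, 1] - t.y).min() <= 3:
                hits += 1
        assert abs(hits - 5) <= 1


class TestFilter:
    def test_border_points_removed(self):
        ms = lm.MinutiaSet(
            (lm.Minutia(2, 2, "termination"), lm.Minutia(50, 50, "bifurcation")),
            image_shape=(100, 100),
        )
        out = lm.filter_minutiae(ms, border_margin=10, min_separation=5)
        assert [m.type for m in out] == ["bifurcation"]

    def test_facing_termination_pair_removed(self):
        ms = lm.MinutiaSet(
            (
                lm.Minutia(50, 50, "termination"),
                lm.Minutia(53, 50, "termination"),
                lm.Minutia(80, 80, "termination"),
            ),
            image_shape=(128, 128),
        )
        out = lm.filter_minutiae(ms, border_margin=10, min_separation=5)
        assert [(m.x, m.y) for m in out] == [(80, 80)]

    def test_well_separated_set_unchanged(self):
        ms = lm.MinutiaSet(
            (
                lm.Minutia(40, 40, "termination"),
                lm.Minutia(90, 40, "bifurcation"),
                lm.Minutia(40, 90, "eye"),
            ),
            image_shape=(128, 128),
        )
        out = lm.filter_minutiae(ms, border_margin=10, min_separation=5)
        assert len(out) == 3
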