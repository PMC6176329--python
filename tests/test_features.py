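"""Descriptor correctness against brute-force and enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinecurve.config import FeatureConfig
from spinecurve.features import (
    FeatureExtractor,
    HaarTemplate,
    Normalizer,
    compute_integral_image,
    extract_feature_vector,
    haar_feature,
    hog_descriptor,
    hog_gradient,
    lbp_code,
    lbp_descriptor,
    rect_sum,
    template_rects,
)

SMALL_CONFIG = FeatureConfig(window=(24, 20))


class TestIntegralImage:
    def test_all_ones_full_rectangle(self):
        ii = compute_integral_image(np.ones((4, 4)))
        assert rect_sum(ii, 0, 0, 4, 4) == 16

    def test_single_pixel(self):
        ii = compute_integral_image(np.array([[7.0]]))
        assert rect_sum(ii, 0, 0, 1, 1) == 7

    def test_random_rectangles_match_bruteforce(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 256, size=(10, 10)).astype(float)
        ii = compute_integral_image(patch)
        for _ in range(50):
            t = int(rng.integers(0, 10))
            l = int(rng.integers(0, 10))
            h = int(rng.integers(1, 11 - t))
            w = int(rng.integers(1, 11 - l))
            brute = sum(patch[r, c] for r in range(t, t + h) for c in range(l, l + w))
            assert rect_sum(ii, t, l, h, w) == brute

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(2, 8), st.integers(0, 2**32 - 1))
    def test_rect_sums_exact_on_integer_patches(self, rows, cols, seed):
        rng = np.random.default_rng(seed)
        patch = rng.integers(-50, 50, size=(rows, cols)).astype(float)
        ii = compute_integral_image(patch)
        assert rect_sum(ii, 0, 0, rows, cols) == patch.sum()
        assert rect_sum(ii, rows // 2, cols // 2, rows - rows // 2, cols - cols // 2) == (
            patch[rows // 2 :, cols // 2 :].sum()
        )


class TestHaar:
    def test_edge_templates_vanish_on_constant_patch(self):
        ii = compute_integral_image(np.full((12, 12), 3.7))
        for kind in ("edge-horizontal", "edge-vertical"):
            assert haar_feature(ii, HaarTemplate(kind, 0, 0, 12, 12)) == pytest.approx(0.0)

    def test_vertical_edge_on_half_bright_patch(self):
        # left half 2, right half 0, white-left template over a 4x4 box
        patch = np.zeros((4, 4))
        patch[:, :2] = 2.0
        ii = compute_integral_image(patch)
        val = haar_feature(ii, HaarTemplate("edge-vertical", 0, 0, 4, 4))
        assert val == pytest.approx(16.0)  # 8 px * 2  -  8 px * 0

    def test_negated_patch_negates_feature(self):
        rng = np.random.default_rng(1)
        patch = rng.normal(size=(16, 16))
        tpl = HaarTemplate("line-horizontal", 2, 2, 12, 9)
        v = haar_feature(compute_integral_image(patch), tpl)
        v_neg = haar_feature(compute_integral_image(-patch), tpl)
        assert v_neg == pytest.approx(-v)

    def test_out_of_bounds_placement_rejected(self):
        ii = compute_integral_image(np.ones((8, 8)))
        with pytest.raises(ValueError):
            haar_feature(ii, HaarTemplate("edge-vertical", 4, 4, 8, 8))

    def test_center_surround_is_white_minus_black(self):
        rng = np.random.default_rng(2)
        patch = rng.normal(size=(9, 9))
        tpl = HaarTemplate("center-surround-1", 0, 0, 9, 9)
        ii = compute_integral_image(patch)
        inner = patch[3:6, 3:6].sum()
        surround = patch.sum() - inner
        assert haar_feature(ii, tpl) == pytest.approx(surround - inner)

    def test_pooled_extraction_matches_single_template_route(self):
        rng = np.random.default_rng(3)
        patch = rng.random(SMALL_CONFIG.window)
        fx = FeatureExtractor(SMALL_CONFIG)
        vec = fx.extract(patch)
        ii = compute_integral_image(patch)
        for idx in (0, 7, len(fx.templates) // 2, len(fx.templates) - 1):
            assert vec[idx] == pytest.approx(haar_feature(ii, fx.templates[idx]))


class TestLbp:
    def test_all_neighbors_above_center(self):
        block = np.full((3, 3), 5.0)
        block[1, 1] = 1.0
        assert lbp_code(block) == 255

    def test_all_neighbors_below_center(self):
        block = np.zeros((3, 3))
        block[1, 1] = 9.0
        assert lbp_code(block) == 0

    @pytest.mark.parametrize("p,expected", [(0, 1), (3, 8)])
    def test_single_bit_positions(self, p, expected):
        from spinecurve.features import LBP_OFFSETS

        block = np.zeros((3, 3))
        block[1, 1] = 5.0
        dr, dc = LBP_OFFSETS[p]
        block[1 + dr, 1 + dc] = 9.0
        assert lbp_code(block) == expected

    def test_exhaustive_256_sign_patterns(self):
        # Independent oracle: build the code directly from the bit pattern.
        from spinecurve.features import LBP_OFFSETS

        for pattern in range(256):
            block = np.zeros((3, 3))
            block[1, 1] = 5.0
            for p, (dr, dc) in enumerate(LBP_OFFSETS):
                block[1 + dr, 1 + dc] = 9.0 if (pattern >> p) & 1 else 1.0
            assert lbp_code(block) == pattern

    def test_constant_patch_codes_are_all_255(self):
        # Ties count as >=, so every interior pixel codes 255.
        hist = lbp_descriptor(np.full((12, 12), 0.4), grid=(2, 2))
        hist = hist.reshape(4, 256)
        assert np.all(hist[:, 255] > 0)
        assert hist.sum() == hist[:, 255].sum()

    def test_histogram_totals_equal_interior_pixel_counts(self):
        rng = np.random.default_rng(4)
        patch = rng.random((13, 14))
        gr, gc = 2, 2
        hist = lbp_descriptor(patch, grid=(gr, gc)).reshape(gr * gc, 256)
        # 11 x 12 interior pixels distributed over the subregion grid
        assert hist.sum() == 11 * 12

    def test_subregion_smaller_than_3x3_rejected(self):
        with pytest.raises(ValueError):
            lbp_descriptor(np.zeros((8, 8)), grid=(4, 4))


class TestHog:
    def test_constant_patch_gives_zero_descriptor(self):
        assert np.all(hog_descriptor(np.full((16, 16), 0.3), cell=8) == 0.0)

    def test_linear_ramp_gradient_is_exact(self):
        patch = np.tile(np.arange(16, dtype=float), (16, 1))  # f(x, y) = x (column)
        fx, fy = hog_gradient(patch)
        assert np.allclose(fx, 1.0)
        assert np.allclose(fy, 0.0)

    def test_vertical_step_edge_dominant_bin_matches_oracle(self):
        patch = np.zeros((16, 16))
        patch[:, 8:] = 1.0
        desc = hog_descriptor(patch, cell=8, bins=9, block=2)
        # Oracle: per-pixel finite differences histogrammed directly.
        fx, fy = hog_gradient(patch)
        mag = np.hypot(fx, fy)
        theta = np.mod(np.arctan2(fy, fx), np.pi)
        idx = np.minimum((theta / np.pi * 9).astype(int), 8)
        oracle = np.zeros(9)
        for b in range(9):
            oracle[b] = mag[idx == b].sum()
        dominant = int(np.argmax(oracle))
        cells = desc.reshape(-1, 9)
        assert int(np.argmax(cells.sum(axis=0))) == dominant

    def test_blocks_are_l2_normalized(self):
        rng = np.random.default_rng(5)
        desc = hog_descriptor(rng.random((24, 24)), cell=8, bins=9, block=2)
        blocks = desc.reshape(-1, 4 * 9)
        norms = np.linalg.norm(blocks, axis=1)
        assert np.allclose(norms[norms > 0], 1.0)

    def test_patch_smaller_than_cell_rejected(self):
        with pytest.raises(ValueError):
            hog_descriptor(np.zeros((4, 4)), cell=8)


class TestFusion:
    def test_vector_length_fixed_and_pure(self):
        fx = FeatureExtractor(SMALL_CONFIG)
        rng = np.random.default_rng(6)
        p1 = rng.random(SMALL_CONFIG.window)
        v1 = fx.extract(p1)
        v2 = fx.extract(p1.copy())
        assert v1.shape == (fx.n_features,)
        assert np.array_equal(v1, v2)
        assert fx.n_features == fx.n_haar + fx.n_lbp + fx.n_hog

    def test_block_order_is_haar_lbp_hog(self):
        fx = FeatureExtractor(SMALL_CONFIG)
        rng = np.random.default_rng(7)
        patch = rng.random(SMALL_CONFIG.window)
        vec = fx.extract(patch)
        lbp_block = vec[fx.block_offsets["lbp"] : fx.block_offsets["hog"]]
        assert np.array_equal(lbp_block, lbp_descriptor(patch, SMALL_CONFIG.lbp_grid))
        hog_block = vec[fx.block_offsets["hog"] :]
        assert np.allclose(
            hog_block,
            hog_descriptor(
                patch, SMALL_CONFIG.hog_cell, SMALL_CONFIG.hog_bins, SMALL_CONFIG.hog_block
            ),
        )

    def test_standardized_training_columns(self):
        fx = FeatureExtractor(SMALL_CONFIG)
        rng = np.random.default_rng(8)
        X = fx.extract_many(rng.random((12, *SMALL_CONFIG.window)))
        norm = Normalizer().fit(X)
        Z = norm.transform(X)
        nonconstant = X.std(axis=0) > 1e-12
        assert np.allclose(Z[:, nonconstant].mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Z[:, nonconstant].std(axis=0), 1.0, atol=1e-10)

    def test_wrong_patch_shape_rejected(self):
        with pytest.raises(ValueError):
            extract_feature_vector(np.zeros((10, 10)), SMALL_CONFIG)

    def test_template_rects_are_disjoint_and_inside(self):
        for tpl in FeatureExtractor(SMALL_CONFIG).templates[:64]:
            covered = np.zeros((tpl.height, tpl.width))
            for _, t, l, h, w in template_rects(tpl):
                rt, rl = t - tpl.top, l - tpl.left
                assert 0 <= rt and 0 <= rl
                assert rt + h <= tpl.height and rl + w <= tpl.width
                if tpl.kind.startswith(("edge", "line")):
                    covered[rt : rt + h, rl : rl + w] += 1
            if tpl.kind.startswith(("edge", "line")):
                assert covered.max() <= 1  # white/black regions never overlap
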