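"""Texture features: grayscale conversion, ROI extraction, first-order
moments, GLCM/GLRLM construction and the 15-feature profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from peelfusion import (
    BUILTIN_IMAGE_SPECS,
    compute_glcm,
    compute_glrlm,
    extract_rois,
    first_order_features,
    generate_texture_image,
    glcm_features,
    glrlm_features,
    texture_profile,
    to_grayscale,
)
from peelfusion.imgtex import FEATURE_NAMES, quantize

from ._oracles import brute_glcm, brute_glcm_features, brute_glrlm, brute_glrlm_features
from .conftest import EXAMPLE_IMG


class TestToGrayscale:
    def test_gray_input_passes_through(self):
        rgb = np.full((4, 4, 3), 97, dtype=np.uint8)
        assert np.all(to_grayscale(rgb) == 97)

    def test_white_maps_to_255(self):
        assert to_grayscale(np.full((2, 2, 3), 255, dtype=np.uint8))[0, 0] == 255

    def test_pure_red_maps_to_bt601_luminance(self):
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        rgb[..., 0] = 255
        assert to_grayscale(rgb)[0, 0] == 76  # round(0.299 * 255)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))


class TestFirstOrder:
    def test_hand_computed_moments(self):
        img = np.array([0, 0, 0, 0, 0, 1, 1, 2, 2]).reshape(3, 3)
        mean, std, _, _ = first_order_features(img)
        assert mean == pytest.approx(0.6667, abs=1e-4)
        assert std == pytest.approx(0.8165, abs=1e-4)

    def test_constant_image_degenerate_conventions(self):
        mean, std, skew, kurt = first_order_features(np.full((5, 5), 9))
        assert (mean, std, skew, kurt) == (9.0, 0.0, 0.0, 0.0)

    def test_symmetric_histogram_has_zero_skewness(self):
        _, _, skew, _ = first_order_features(np.array([[0, 1], [1, 2]]))
        assert skew == pytest.approx(0.0, abs=1e-12)


class TestGLCM:
    def test_hand_enumerated_horizontal_pairs(self):
        P = compute_glcm(EXAMPLE_IMG, angles=(0.0,), levels=3).P
        expected = np.array([[4, 2, 1], [2, 0, 0], [1, 0, 2]]) / 12.0
        assert np.allclose(P, expected)

    def test_hand_computed_features_of_example(self):
        feats = glcm_features(compute_glcm(EXAMPLE_IMG, angles=(0.0,), levels=3))
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["dissimilarity"] == pytest.approx(0.6667, abs=1e-4)
        assert feats["asm"] == pytest.approx(0.2083, abs=1e-4)
        assert feats["energy"] == pytest.approx(np.sqrt(feats["asm"]))
        assert feats["homogeneity"] == pytest.approx(0.70, abs=1e-10)

    def test_constant_image_degeneracies(self):
        img = np.full((6, 6), 3, dtype=np.uint8)
        feats = glcm_features(compute_glcm(img, levels=8))
        assert feats["contrast"] == 0.0
        assert feats["homogeneity"] == pytest.approx(1.0)
        assert feats["asm"] == pytest.approx(1.0)
        assert feats["correlation"] == 1.0  # sigma = 0 convention

    def test_checkerboard_contrast_and_anticorrelation(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        feats = glcm_features(compute_glcm(img.astype(np.uint8), angles=(0.0,), levels=2))
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["correlation"] == pytest.approx(-1.0)

    def test_unquantized_input_rejected(self):
        with pytest.raises(ValueError, match="quantize"):
            compute_glcm(np.array([[0, 200], [1, 2]]), levels=3)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(np.ones((3, 3)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(np.uint8, (5, 7), elements=st.integers(0, 7)))
    def test_probability_conservation_and_symmetry(self, img):
        P = compute_glcm(img, levels=8).P
        assert np.isclose(P.sum(), 1.0)
        assert np.allclose(P, P.T)


class TestGLRLM:
    def test_hand_enumerated_horizontal_runs(self):
        rlm = compute_glrlm(EXAMPLE_IMG, directions=(0,), levels=3)
        assert rlm.r[0, 1] == 2  # two runs of level 0, length 2
        assert rlm.r[1, 0] == 2
        assert rlm.r[0, 0] == 1
        assert rlm.r[2, 1] == 1
        assert rlm.n_runs == 6

    def test_pixel_conservation(self):
        rlm = compute_glrlm(EXAMPLE_IMG, directions=(0,), levels=3)
        j = np.arange(1, rlm.r.shape[1] + 1)
        assert (rlm.r * j).sum() == 9

    def test_constant_row_image_single_runs(self):
        rlm = compute_glrlm(np.full((4, 4), 2, dtype=np.uint8), directions=(0,), levels=3)
        assert rlm.r[2, 3] == 4
        assert rlm.n_runs == 4

    def test_hand_computed_features_of_example(self):
        feats = glrlm_features(compute_glrlm(EXAMPLE_IMG, directions=(0,), levels=3))
        assert feats["sre"] == pytest.approx(0.625)
        assert feats["lre"] == pytest.approx(2.5)
        assert feats["gln"] == pytest.approx(2.3333, abs=1e-4)
        assert feats["rln"] == pytest.approx(3.0)
        assert feats["rp"] == pytest.approx(0.6667, abs=1e-4)

    def test_single_run_of_length_four(self):
        rlm = compute_glrlm(np.array([[1, 1, 1, 1]], dtype=np.uint8),
                            directions=(0,), levels=2)
        feats = glrlm_features(rlm)
        assert feats["sre"] == pytest.approx(1 / 16)
        assert feats["lre"] == pytest.approx(16.0)
        assert feats["rp"] == pytest.approx(1 / 4)

    def test_all_distinct_pixels_give_unit_emphases(self):
        img = np.arange(4, dtype=np.uint8).reshape(2, 2)
        feats = glrlm_features(compute_glrlm(img, directions=(0,), levels=4))
        assert feats["sre"] == feats["lre"] == feats["rp"] == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(np.uint8, (6, 5), elements=st.integers(0, 3)))
    def test_pixel_conservation_per_direction(self, img):
        for d in (0, 45, 90, 135):
            rlm = compute_glrlm(img, directions=(d,), levels=4)
            j = np.arange(1, rlm.r.shape[1] + 1)
            assert (rlm.r * j).sum() == img.size


class TestBruteForceEquivalence:
    """Spot equivalence with the independent enumerator (the exhaustive
    10^4-image sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(25))
    def test_glcm_and_glrlm_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, size=2))
        img = rng.integers(0, 3, size=shape).astype(np.uint8)
        ours = glcm_features(compute_glcm(img, levels=3))
        ref = brute_glcm_features(brute_glcm(img, 3))
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, abs=1e-12), k
        rlm = compute_glrlm(img, levels=3)
        ref_r = brute_glrlm(img, 3)
        assert np.array_equal(rlm.r, ref_r)
        ours_rl = glrlm_features(rlm)
        ref_rl = brute_glrlm_features(ref_r, img.size * 4)
        for k, v in ref_rl.items():
            assert ours_rl[k] == pytest.approx(v, abs=1e-12), k


class TestExtractROIs:
    def test_grid_of_four_is_corner_aligned(self):
        img = np.zeros((256, 256))
        rois = extract_rois(img, roi_size=64, k=4, strategy="grid")
        corners = {(r.row0, r.col0) for r in rois}
        assert corners == {(0, 0), (0, 192), (192, 0), (192, 192)}

    def test_single_roi_is_centered(self):
        roi = extract_rois(np.zeros((100, 100)), roi_size=64, k=1, strategy="grid")[0]
        assert (roi.row0, roi.col0) == (18, 18)

    def test_random_strategy_is_seeded_and_non_overlapping(self):
        img = np.zeros((256, 256))
        a = extract_rois(img, 64, 4, strategy="random", seed=3)
        b = extract_rois(img, 64, 4, strategy="random", seed=3)
        assert a == b
        for i, r1 in enumerate(a):
            for r2 in a[i + 1:]:
                assert abs(r1.row0 - r2.row0) >= 64 or abs(r1.col0 - r2.col0) >= 64

    def test_oversized_roi_and_infeasible_k_rejected(self):
        with pytest.raises(ValueError):
            extract_rois(np.zeros((32, 32)), roi_size=64, k=1)
        with pytest.raises(ValueError, match="non-overlapping"):
            extract_rois(np.zeros((128, 128)), roi_size=64, k=5, strategy="grid")


class TestTextureProfile:
    def test_constant_image_degenerate_record(self):
        prof = texture_profile(np.full((128, 128), 50, dtype=np.uint8))
        m = prof.mean
        assert (m.std, m.skewness, m.kurtosis, m.contrast) == (0.0, 0.0, 0.0, 0.0)
        assert m.homogeneity == m.asm == m.correlation == 1.0
        assert m.mean_intensity == 50.0

    def test_energy_squared_equals_asm_per_roi(self):
        img = generate_texture_image(BUILTIN_IMAGE_SPECS["orange"], seed=2)
        prof = texture_profile(img)
        assert np.allclose(prof.per_roi["energy"] ** 2, prof.per_roi["asm"], atol=1e-12)

    def test_fifteen_canonical_features_reported(self):
        prof = texture_profile(np.full((64, 64), 10, dtype=np.uint8), k=1)
        assert tuple(prof.per_roi.columns) == FEATURE_NAMES

    def test_uniform_class_is_more_homogeneous_than_blotchy_class(self):
        uni = generate_texture_image(BUILTIN_IMAGE_SPECS["lemon"], seed=5)
        blotchy = generate_texture_image(BUILTIN_IMAGE_SPECS["clementine"], seed=5)
        fu, fb = texture_profile(uni).mean, texture_profile(blotchy).mean
        assert fu.homogeneity > fb.homogeneity
        assert fu.rln < fb.rln

    def test_quantize_full_range_to_32_levels(self):
        img = np.array([[0, 255], [128, 8]], dtype=np.uint8)
        q = quantize(img, 32)
        assert q.tolist() == [[0, 31], [16, 1]]
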