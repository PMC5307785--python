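import numpy as np
import pytest

import petresponse as pr
from petresponse.errors import DataError
from petresponse.features import (
    DB4_DEC_HI,
    DB4_DEC_LO,
    FAMILY_SIZES,
    FEATURE_NAMES,
    GLCM_NAMES,
    UNIFORM_LBP_CODES,
    WAVELET_SUBBANDS,
    _dwt2,
    _gabor_bank,
    gabor_features,
    glcm_features,
    glrl_features,
    histogram_features,
    lbp_features,
    quantize_roi,
    wavelet_features,
)

from conftest import random_roi
import oracles


class TestLayout:
    def test_family_sizes_and_total(self):
        assert FAMILY_SIZES == {
            "histogram": 4, "glcm": 22, "glrl": 11,
            "wavelet": 28, "gabor": 48, "lbp": 58,
        }
        assert sum(FAMILY_SIZES.values()) == 171
        assert len(FEATURE_NAMES) == 171
        assert len(set(FEATURE_NAMES)) == 171

    def test_uniform_codes_are_58(self):
        assert len(UNIFORM_LBP_CODES) == 58


class TestHistogram:
    def test_constant_roi_convention(self):
        img = np.full((4, 4), 0.3)
        mask = np.ones((4, 4), dtype=bool)
        assert np.allclose(histogram_features(img, mask), [0.3, 0.0, 0.0, 0.0])

    def test_bernoulli_half(self):
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        mask = np.ones((2, 2), dtype=bool)
        mean, var, _, _ = histogram_features(img, mask)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.25)

    def test_hand_computed_example(self):
        img = np.array([[0.2, 0.4], [0.4, 1.0]])
        mask = np.ones((2, 2), dtype=bool)
        got = histogram_features(img, mask)
        expected = oracles.histogram_moments([0.2, 0.4, 0.4, 1.0])
        assert np.allclose(got, expected, rtol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            histogram_features(np.ones((3, 3)), np.zeros((3, 3), dtype=bool))


class TestGlcm:
    def test_constant_roi_single_cell(self):
        roi = quantize_roi(np.full((4, 4), 0.5), np.ones((4, 4), dtype=bool))
        stats = dict(zip(GLCM_NAMES, glcm_features(roi)))
        assert stats["angular_second_moment"] == pytest.approx(1.0)
        assert stats["entropy"] == pytest.approx(0.0)
        assert stats["contrast"] == pytest.approx(0.0)

    def test_block_length_22(self):
        rng = np.random.default_rng(1)
        img, mask = random_roi(rng)
        assert len(glcm_features(quantize_roi(img, mask))) == 22

    def test_checkerboard_contrast_by_pair_enumeration(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 / 1.0
        mask = np.ones((4, 4), dtype=bool)
        roi = quantize_roi(img, mask, n_levels=2)
        got = dict(zip(GLCM_NAMES, glcm_features(roi)))["contrast"]
        expected = oracles.glcm_features_bruteforce(roi.pixels, roi.mask, 2)[1]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_average_matrix_symmetric_and_normalized(self):
        rng = np.random.default_rng(7)
        from petresponse.features import glcm_matrix

        img, mask = random_roi(rng)
        roi = quantize_roi(img, mask)
        mats = [glcm_matrix(roi, d) for d in (0, 45, 90, 135)]
        avg = np.mean([m for m in mats if m is not None], axis=0)
        assert np.allclose(avg, avg.T)
        assert avg.sum() == pytest.approx(1.0)

    def test_oracle_agreement_random_rois(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            img, mask = random_roi(rng)
            roi = quantize_roi(img, mask)
            got = glcm_features(roi)
            expected = oracles.glcm_features_bruteforce(roi.pixels, roi.mask, roi.n_levels)
            np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)


class TestGlrl:
    def test_block_length_11(self):
        rng = np.random.default_rng(2)
        img, mask = random_roi(rng)
        assert len(glrl_features(quantize_roi(img, mask))) == 11

    def test_single_row_constant_run(self):
        img = np.full((1, 6), 0.5)
        mask = np.ones((1, 6), dtype=bool)
        roi = quantize_roi(img, mask)
        stats = glrl_features(roi, directions=(0,))
        rp = stats[4]
        assert rp == pytest.approx(1 / 6)  # one run of length = row length

    def test_two_runs_of_two(self):
        img = np.array([[0.0, 0.0, 1.0, 1.0]])
        mask = np.ones((1, 4), dtype=bool)
        roi = quantize_roi(img, mask, n_levels=2)
        sre, lre = glrl_features(roi, directions=(0,))[:2]
        # two runs of length 2: SRE = (2 * 1/4) / 2 = 1/4, LRE = (2 * 4) / 2 = 4
        assert sre == pytest.approx(0.25)
        assert lre == pytest.approx(4.0)

    def test_oracle_agreement_random_rois(self):
        rng = np.random.default_rng(321)
        for _ in range(20):
            img, mask = random_roi(rng)
            roi = quantize_roi(img, mask)
            got = glrl_features(roi)
            expected = oracles.glrl_features_bruteforce(roi.pixels, roi.mask, roi.n_levels)
            np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)


class TestWavelet:
    def test_block_length_28(self):
        rng = np.random.default_rng(3)
        assert len(wavelet_features(rng.random((12, 12)))) == 28

    def test_filters_are_quadrature_pair(self):
        assert np.allclose(DB4_DEC_LO.sum(), np.sqrt(2))
        assert abs(DB4_DEC_HI.sum()) < 1e-12

    def test_constant_image_zero_detail(self):
        feats = dict(zip(
            [f"{s}.{b}" for b in WAVELET_SUBBANDS for s in ("mean_abs", "std", "energy", "entropy")],
            wavelet_features(np.full((10, 10), 0.7)),
        ))
        for band in ("LH1", "HL1", "HH1", "LH2", "HL2", "HH2"):
            assert feats[f"mean_abs.{band}"] == pytest.approx(0.0, abs=1e-12)
            assert feats[f"energy.{band}"] == pytest.approx(0.0, abs=1e-12)

    def test_ramp_subbands_match_filter_bank_oracle(self):
        img = np.tile(np.linspace(0, 1, 16), (16, 1))
        level1 = _dwt2(img)
        expected = oracles.dwt2_bruteforce(img, DB4_DEC_LO.tolist(), DB4_DEC_HI.tolist())
        for band in ("LL", "LH", "HL", "HH"):
            np.testing.assert_allclose(level1[band], expected[band], rtol=1e-9, atol=1e-12)

    def test_full_feature_oracle_random_rois(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            img = rng.random((12, 12))
            got = wavelet_features(img)
            l1 = oracles.dwt2_bruteforce(img, DB4_DEC_LO.tolist(), DB4_DEC_HI.tolist())
            l2 = oracles.dwt2_bruteforce(l1["LL"], DB4_DEC_LO.tolist(), DB4_DEC_HI.tolist())
            bands = {"LH1": l1["LH"], "HL1": l1["HL"], "HH1": l1["HH"],
                     "LH2": l2["LH"], "HL2": l2["HL"], "HH2": l2["HH"], "LL2": l2["LL"]}
            expected = np.concatenate(
                [oracles.subband_stats_bruteforce(bands[b]) for b in WAVELET_SUBBANDS]
            )
            np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_too_small_roi_names_minimum(self):
        with pytest.raises(DataError, match="4x4"):
            wavelet_features(np.ones((3, 8)))


class TestGabor:
    def test_block_length_48_and_12_filters(self):
        rng = np.random.default_rng(4)
        assert len(gabor_features(rng.random((12, 12)))) == 48
        assert len(_gabor_bank((0.4, 0.2, 0.1), (0, 45, 90, 135))) == 12

    def test_constant_image_zero_response(self):
        feats = gabor_features(np.full((16, 16), 0.6))
        # DC-free kernels: means/stds/energies all ~0
        assert np.allclose(feats, 0.0, atol=1e-10)

    def test_magnitude_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.random((10, 10))
        from petresponse.features import GABOR_FREQUENCIES, GABOR_ORIENTATIONS_DEG

        bank = _gabor_bank(GABOR_FREQUENCIES, GABOR_ORIENTATIONS_DEG)
        got = gabor_features(img).reshape(12, 4)
        for idx, (real, imag) in enumerate(bank):
            mag = oracles.gabor_magnitude_bruteforce(img, real, imag)
            stats = [mag.mean(), mag.std(), (mag**2).sum()]
            np.testing.assert_allclose(got[idx, :3], stats, rtol=1e-9, atol=1e-12)


class TestLbp:
    def test_block_length_58(self):
        rng = np.random.default_rng(6)
        assert len(lbp_features(rng.random((8, 8)))) == 58

    def test_constant_image_single_bin(self):
        hist = lbp_features(np.full((6, 6), 0.4))
        # ties produce the all-ones pattern (code 255), which is uniform
        assert hist.sum() == pytest.approx(1.0)
        assert hist[UNIFORM_LBP_CODES.index(255)] == pytest.approx(1.0)
        assert (hist > 0).sum() == 1

    def test_histogram_properties(self):
        rng = np.random.default_rng(8)
        hist = lbp_features(rng.random((10, 10)))
        assert ((hist >= 0) & (hist <= 1)).all()
        assert hist.sum() == pytest.approx(1.0) or np.allclose(hist, 0.0)

    def test_oracle_agreement_random_images(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            img = rng.random((8, 8))
            np.testing.assert_allclose(
                lbp_features(img), oracles.lbp_histogram_bruteforce(img), rtol=1e-12
            )

    def test_too_small_rejected(self):
        with pytest.raises(DataError):
            lbp_features(np.ones((2, 5)))


class TestExtractAll:
    def test_length_and_determinism(self):
        rng = np.random.default_rng(10)
        img, mask = random_roi(rng, size=20)
        v1 = pr.extract_all(img, mask)
        v2 = pr.extract_all(img, mask)
        assert len(v1) == 171
        assert np.array_equal(v1.values, v2.values)

    def test_translation_invariance(self):
        rng = np.random.default_rng(12)
        patch = rng.random((9, 9))
        pmask = rng.random((9, 9)) < 0.8
        pmask[4, 4] = True
        big1 = np.zeros((30, 30)); big2 = np.zeros((30, 30))
        m1 = np.zeros((30, 30), dtype=bool); m2 = np.zeros((30, 30), dtype=bool)
        big1[2:11, 3:12] = patch; m1[2:11, 3:12] = pmask
        big2[15:24, 18:27] = patch; m2[15:24, 18:27] = pmask
        assert np.array_equal(pr.extract_all(big1, m1).values, pr.extract_all(big2, m2).values)

    def test_background_outside_mask_irrelevant(self):
        rng = np.random.default_rng(13)
        img, mask = random_roi(rng, size=14)
        noisy = img.copy()
        noisy[~mask] = rng.random((~mask).sum())  # scramble background
        # matrix families see only in-mask pixels; bbox-level families
        # (wavelet/gabor/lbp) see the bbox, so compare the mask families
        roi_a = quantize_roi(img, mask)
        roi_b = quantize_roi(noisy, mask)
        np.testing.assert_allclose(glcm_features(roi_a), glcm_features(roi_b), rtol=1e-12)
        np.testing.assert_allclose(glrl_features(roi_a), glrl_features(roi_b), rtol=1e-12)
        np.testing.assert_allclose(
            histogram_features(img, mask), histogram_features(noisy, mask), rtol=1e-12
        )

    def test_quantization_levels(self):
        rng = np.random.default_rng(14)
        img, mask = random_roi(rng)
        roi = quantize_roi(img, mask, n_levels=8)
        assert roi.pixels[roi.mask].min() >= 1
        assert roi.pixels[roi.mask].max() <= 8
        assert (roi.pixels[~roi.mask] == 0).all()
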