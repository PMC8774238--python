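"""Texture-feature classes: worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest

from peritex.features import (
    ExtractionProfile,
    Offset,
    ar_model,
    extract_all,
    feature_map,
    glcm,
    glcm_features,
    gradient_features,
    histogram_features,
    rlm_features,
    wavelet_energies,
)
from peritex.imaging import GrayImage, QuantizedROI, ROIMask, normalize_and_quantize

from _oracles import (
    brute_glcm,
    brute_glcm_features,
    brute_rlm_features,
    haar_dwt2_oracle,
)
from conftest import random_quantized


def make_q(levels, ng=None, mask=None):
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    ng = ng or int(levels.max())
    return QuantizedROI(
        levels=np.where(mask, levels, 0).astype(np.int32),
        mask=np.asarray(mask, dtype=bool),
        n_levels=ng,
        norm_stats=(0, 1, -3, 3),
    )


class TestHistogram:
    def test_worked_example(self):
        q = make_q([[1, 1], [2, 2]], ng=4)
        fv = histogram_features(q, percentiles=(10,))
        assert fv["Hist_Mean"] == 1.5
        assert fv["Hist_Variance"] == 0.25
        assert fv["Hist_Skewness"] == 0.0
        assert fv["Hist_Perc10"] == 1

    def test_constant_roi_moments_undefined(self):
        fv = histogram_features(make_q([[3, 3], [3, 3]], ng=4))
        assert fv["Hist_Variance"] == 0.0
        assert np.isnan(fv["Hist_Skewness"])
        assert "zero variance" in fv.reason("Hist_Skewness")

    def test_perc100_is_max_level(self, rng):
        q = random_quantized(rng, ng=16)
        fv = histogram_features(q, percentiles=(100,))
        assert fv["Hist_Perc100"] == q.in_mask_levels.max()

    def test_percentile_definition_against_sorted_counts(self, rng):
        # smallest level v with >= n% of pixels <= v
        q = random_quantized(rng, shape=(10, 10), ng=6)
        lv = np.sort(q.in_mask_levels)
        for p in (1, 10, 50, 90, 99):
            v = histogram_features(q, percentiles=(p,))[f"Hist_Perc{p}"]
            assert np.mean(lv <= v) >= p / 100.0
            if v > 1:
                assert np.mean(lv <= v - 1) < p / 100.0


class TestGLCM:
    def test_two_column_pattern(self):
        q = make_q([[1, 2], [1, 2]])
        P = glcm(q, Offset("H", 1))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)

    def test_uniform_image_single_cell(self):
        q = make_q([[2, 2], [2, 2]], ng=4)
        P = glcm(q, Offset("H", 1))
        assert P[1, 1] == 1.0
        fv = glcm_features(P)
        assert fv["Contrast"] == 0.0
        assert fv["AngScMom"] == 1.0
        assert fv["Entropy"] == 0.0
        assert fv["InvDfMom"] == 1.0
        assert np.isnan(fv["Correlat"])  # zero marginal variance

    def test_checkerboard(self):
        board = 1 + (np.indices((6, 6)).sum(axis=0) % 2)
        fv = glcm_features(glcm(make_q(board), Offset("H", 1)))
        assert fv["Contrast"] == pytest.approx(1.0)
        assert fv["AngScMom"] == pytest.approx(0.5)
        assert fv["Entropy"] == pytest.approx(np.log(2))
        assert fv["InvDfMom"] == pytest.approx(0.5)

    def test_matrix_sums_to_one(self, rng):
        q = random_quantized(rng)
        for d in "HVNZ":
            assert glcm(q, Offset(d, 1)).sum() == pytest.approx(1.0)

    def test_no_valid_pairs_names_offset(self):
        q = make_q([[1, 0, 2], [0, 0, 0], [2, 0, 1]], ng=4)
        with pytest.raises(ValueError, match="H d=1"):
            glcm(q, Offset("H", 1))

    @pytest.mark.parametrize("direction", ["H", "V", "N", "Z"])
    @pytest.mark.parametrize("distance", [1, 3])
    def test_oracle_equivalence(self, rng, direction, distance):
        """Fast GLCM path equals explicit O(N^2) pair enumeration."""
        for _ in range(12):
            q = random_quantized(rng, shape=(9, 9), ng=6, mask_fraction=0.75)
            try:
                P = glcm(q, Offset(direction, distance))
            except ValueError:
                continue
            P_ref = brute_glcm(q.levels, q.mask, direction, distance, 6)
            assert np.allclose(P, P_ref, atol=1e-12)
            got = glcm_features(P)
            want = brute_glcm_features(P_ref)
            for name, ref in want.items():
                assert got[name] == pytest.approx(ref, abs=1e-10), name

    def test_rotation_covariance(self, rng):
        """Rotating the grid by 90 degrees swaps H<->V and N<->Z exactly."""
        q = random_quantized(rng, shape=(10, 10), ng=8)
        rot = QuantizedROI(
            levels=np.rot90(q.levels).copy(),
            mask=np.rot90(q.mask).copy(),
            n_levels=q.n_levels,
            norm_stats=q.norm_stats,
        )
        pairs = {"H": "V", "V": "H", "N": "Z", "Z": "N"}
        for d, d_rot in pairs.items():
            f1 = glcm_features(glcm(q, Offset(d, 2)))
            f2 = glcm_features(glcm(rot, Offset(d_rot, 2)))
            for name in f1.names:
                if not np.isnan(f1[name]):
                    assert f1[name] == pytest.approx(f2[name], abs=1e-12)

    def test_invariant_to_hu_offset(self, rng):
        vals = rng.normal(40, 8, (16, 16))
        roi = ROIMask(np.ones((16, 16), dtype=bool))
        q1 = normalize_and_quantize(GrayImage(vals), roi, bits=6)
        q2 = normalize_and_quantize(GrayImage(vals + 500.0), roi, bits=6)
        f1 = glcm_features(glcm(q1, Offset("N", 2)))
        f2 = glcm_features(glcm(q2, Offset("N", 2)))
        for name in f1.names:
            assert f1[name] == pytest.approx(f2[name], nan_ok=True)

    def test_feature_bounds(self, rng):
        for _ in range(10):
            q = random_quantized(rng, ng=8)
            fv = glcm_features(glcm(q, Offset("H", 1)))
            assert fv["Entropy"] >= 0 and fv["SumEntrp"] >= 0 and fv["DifEntrp"] >= 0
            assert 0 < fv["AngScMom"] <= 1
            assert 0 < fv["InvDfMom"] <= 1


class TestRLM:
    def test_constant_rows(self):
        fv = rlm_features(make_q(np.full((4, 4), 3), ng=8), "H")
        assert fv["RLM_H_LngREmph"] == 16.0
        assert fv["RLM_H_ShrtREmp"] == pytest.approx(1 / 16)
        assert fv["RLM_H_GLevNonU"] == 4.0
        assert fv["RLM_H_RLNonUni"] == 4.0
        assert fv["RLM_H_Fraction"] == 0.25

    def test_alternating_rows_all_length_one(self):
        row = np.tile([1, 2], 4)
        q = make_q(np.tile(row, (4, 1)), ng=4)
        fv = rlm_features(q, "H")
        assert fv["RLM_H_ShrtREmp"] == 1.0
        assert fv["RLM_H_LngREmph"] == 1.0
        assert fv["RLM_H_Fraction"] == 1.0

    @pytest.mark.parametrize("direction", ["H", "V", "N", "Z"])
    def test_oracle_equivalence(self, rng, direction):
        """Run enumeration matches the brute-force line walker."""
        for _ in range(12):
            q = random_quantized(rng, shape=(9, 9), ng=4, mask_fraction=0.7)
            got = rlm_features(q, direction)
            want = brute_rlm_features(q.levels, q.mask, direction)
            for name, ref in want.items():
                assert got[f"RLM_{direction}_{name}"] == pytest.approx(ref, abs=1e-10)

    def test_fraction_in_unit_interval(self, rng):
        for _ in range(10):
            q = random_quantized(rng)
            for d in "HVNZ":
                assert 0 < rlm_features(q, d)[f"RLM_{d}_Fraction"] <= 1


class TestGradient:
    def test_uniform_roi(self):
        img = GrayImage(np.full((8, 8), 5.0))
        fv = gradient_features(img, ROIMask(np.ones((8, 8), dtype=bool)))
        assert fv["Grad_GrMean"] == 0.0
        assert fv["Grad_GrNonZeros"] == 0.0

    def test_constant_slope_level_ramp(self):
        # a level grid increasing by 1 per row has G = 1 at every interior
        # pixel: zero variance, all gradients nonzero
        from peritex.features.gradient import gradient_from_levels

        fv = gradient_from_levels(
            make_q(np.tile(np.arange(1, 17)[:, None], (1, 16)), ng=16)
        )
        assert fv["Grad_GrMean"] == pytest.approx(1.0)
        assert fv["Grad_GrVariance"] == pytest.approx(0.0)
        assert fv["Grad_GrNonZeros"] == 1.0

    def test_matches_per_pixel_oracle(self, rng):
        vals = rng.normal(0, 5, (10, 10))
        mask = np.ones((10, 10), dtype=bool)
        img = GrayImage(vals)
        fv = gradient_features(img, ROIMask(mask))
        lv = normalize_and_quantize(img, ROIMask(mask), bits=4).levels.astype(float)
        gs = []
        for r in range(1, 9):
            for c in range(1, 9):
                dr = (lv[r + 1, c] - lv[r - 1, c]) / 2
                dc = (lv[r, c + 1] - lv[r, c - 1]) / 2
                gs.append(np.hypot(dr, dc))
        gs = np.array(gs)
        assert fv["Grad_GrMean"] == pytest.approx(gs.mean())
        assert fv["Grad_GrVariance"] == pytest.approx(gs.var())
        assert fv["Grad_GrNonZeros"] == pytest.approx(np.mean(gs > 0))

    def test_no_interior_pixel_undefined(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, :] = True  # a line has no full 4-neighborhood
        fv = gradient_features(GrayImage(np.random.default_rng(0).normal(0, 1, (8, 8))),
                               ROIMask(mask))
        assert np.isnan(fv["Grad_GrMean"])
        assert fv.reason("Grad_GrMean") is not None


class TestARModel:
    def test_recovers_causal_coefficient(self):
        # synthesize a causal lattice x = 0.5 x_left + e row by row
        rng = np.random.default_rng(7)
        n = 60
        x = np.zeros((n, n))
        for r in range(n):
            for c in range(n):
                left = x[r, c - 1] if c else 0.0
                x[r, c] = 0.5 * left + rng.normal(0, 1)
        q = QuantizedROI(
            levels=np.round(x * 100).astype(np.int32) + 1000,
            mask=np.ones((n, n), dtype=bool),
            n_levels=4096,
            norm_stats=(0, 1, -3, 3),
        )
        fv = ar_model(q)
        assert fv["AR_Teta1"] == pytest.approx(0.5, abs=0.05)
        for name in ("AR_Teta2", "AR_Teta3", "AR_Teta4"):
            assert abs(fv[name]) < 0.05

    def test_white_noise_thetas_near_zero(self):
        rng = np.random.default_rng(3)
        q = make_q(rng.integers(1, 17, (50, 50)), ng=16)
        fv = ar_model(q)
        n_eff = 48 * 48
        se = 1 / np.sqrt(n_eff)  # approximate standard error under the null
        for name in ("AR_Teta1", "AR_Teta2", "AR_Teta3", "AR_Teta4"):
            assert abs(fv[name]) < 3 * se
        assert fv["AR_Sigma"] == pytest.approx(q.in_mask_levels.std(), rel=0.05)

    def test_constant_roi_degenerate(self):
        fv = ar_model(make_q(np.full((10, 10), 5), ng=8))
        assert fv["AR_Sigma"] == 0.0
        assert np.isnan(fv["AR_Teta1"])

    def test_too_few_pixels_undefined(self):
        fv = ar_model(make_q(np.arange(1, 10).reshape(3, 3), ng=16))
        assert np.isnan(fv["AR_Sigma"])
        assert "fewer than" in fv.reason("AR_Sigma")


class TestWavelet:
    def test_constant_roi_zero_detail(self):
        q = make_q(np.full((32, 32), 4), ng=8)
        fv = wavelet_energies(q, scales=5)
        for s in range(1, 6):
            for b in ("LH", "HL", "HH"):
                assert fv[f"WavEn_{b}_s{s}"] == pytest.approx(0.0)

    def test_stripes_orientation(self):
        # horizontal stripes of period 2: all level-1 detail lies in the band
        # that is high-pass along rows (HL under this package's labeling)
        stripes = np.tile(np.array([[1], [3]]), (8, 16))
        fv = wavelet_energies(make_q(stripes, ng=4), scales=2)
        assert fv["WavEn_HL_s1"] > 0
        assert fv["WavEn_LH_s1"] == pytest.approx(0.0)
        assert fv["WavEn_HH_s1"] == pytest.approx(0.0)

    def test_matches_direct_haar_oracle(self, rng):
        arr = rng.integers(1, 9, (16, 16))
        q = make_q(arr, ng=8)
        fv = wavelet_energies(q, scales=1)
        ref = haar_dwt2_oracle(arr)
        for band in ("LL", "LH", "HL", "HH"):
            assert fv[f"WavEn_{band}_s1"] == pytest.approx(
                np.mean(ref[band] ** 2), abs=1e-10
            )

    def test_parseval_at_scale_1(self, rng):
        arr = rng.integers(1, 17, (16, 16))
        fv = wavelet_energies(make_q(arr, ng=16), scales=1)
        total = sum(fv[f"WavEn_{b}_s1"] * 64 for b in ("LL", "LH", "HL", "HH"))
        assert total == pytest.approx(np.sum(arr.astype(float) ** 2))

    def test_small_roi_deep_scales_undefined(self):
        q = make_q(np.arange(1, 17).reshape(4, 4), ng=16)
        fv = wavelet_energies(q, scales=5)
        assert not np.isnan(fv["WavEn_HH_s1"])
        assert np.isnan(fv["WavEn_HH_s5"])
        assert "scale 5" in fv.reason("WavEn_HH_s5")


class TestExtractAll:
    def test_default_profile_counts(self, rng):
        img = GrayImage(rng.normal(30, 10, (64, 64)))
        roi = ROIMask(np.ones((64, 64), dtype=bool))
        fv = extract_all(img, roi)
        names = fv.names
        assert len(names) == 275
        by_class = {
            "GLCM": 220,
            "RLM": 20,
            "WavEn": 20,
            "Hist": 5,
            "Grad": 5,
            "AR": 5,
        }
        for cls, n in by_class.items():
            assert sum(name.startswith(cls + "_") for name in names) == n
        assert fv.names == ExtractionProfile().expected_names()

    def test_mazda_aliases_resolve(self, rng):
        img = GrayImage(rng.normal(30, 10, (32, 32)))
        fv = extract_all(img, ROIMask(np.ones((32, 32), dtype=bool)))
        assert fv["Perc10"] == fv["Hist_Perc10"]
        assert fv["CN6D4Contrast"] == fv["GLCM_N_d4_Contrast"]
        assert fv["RZD5GLevNonU"] == fv["RLM_Z_GLevNonU"]
        assert fv["WavEnHH_s-2"] == fv["WavEn_HH_s2"]

    def test_undefined_values_propagate_without_abort(self, rng):
        # tiny ROI: deep wavelet scales and the AR model drop out, the rest
        # is still produced
        img = GrayImage(rng.normal(0, 1, (16, 16)))
        mask = np.zeros((16, 16), dtype=bool)
        mask[6:10, 6:10] = True
        fv = extract_all(img, ROIMask(mask))
        assert len(fv) == 275
        assert np.isnan(fv["WavEn_HH_s5"])
        assert not np.isnan(fv["Hist_Mean"])


class TestFeatureMap:
    def test_contrast_map_of_uniform_image_is_zero(self):
        img = GrayImage(np.full((12, 12), 9.0))
        out = feature_map(img, 5, "GLCM_H_d1_Contrast")
        inner = out[2:-2, 2:-2]
        assert np.all(inner == 0.0)
        assert np.all(np.isnan(out[:2, :]))  # undefined margin

    def test_center_value_matches_window_extraction(self, rng):
        vals = rng.normal(0, 5, (9, 9))
        img = GrayImage(vals)
        out = feature_map(img, 9, "RLM_H_GLevNonU")
        fv = extract_all(
            img,
            ROIMask(np.ones((9, 9), dtype=bool)),
            profile=ExtractionProfile(feature_classes=("RLM",), rlm_directions=("H",)),
        )
        assert out[4, 4] == pytest.approx(fv["RLM_H_GLevNonU"])

    def test_nonuniformity_map_separates_blobby_from_smooth(self):
        """GLevNonU runs higher over a blob-textured patch than a smooth one."""
        rng = np.random.default_rng(11)
        img = np.zeros((20, 40))
        img[:, :20] = rng.choice([0.0, 30.0], size=(20, 20), p=[0.8, 0.2])
        img[:, 20:] = rng.normal(15, 1.0, (20, 20))
        out = feature_map(GrayImage(img), 7, "RZD5GLevNonU")
        blobby = np.nanmedian(out[:, :17])
        smooth = np.nanmedian(out[:, 23:])
        assert blobby > smooth

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            feature_map(GrayImage(np.zeros((8, 8))), 3, "NotAFeature")
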