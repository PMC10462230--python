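import numpy as np
import pytest

from tmegraph.texture_features import (
    GLCM_LEVELS,
    FeatureRegistry,
    extract_features,
    filter_features,
    gabor_features,
    glcm_features,
    glcm_matrix,
    histogram_features,
    lbp_features,
    quantize,
    tamura_features,
)

from _oracles import GLCM_OFFSETS, brute_glcm, brute_glcm_props, brute_lbp_uniform_hist

PROPS = ("contrast", "correlation", "energy", "homogeneity", "entropy")


def _levels_image(rng, shape=(8, 8), n_levels=GLCM_LEVELS):
    return rng.integers(0, n_levels, size=shape)


def _img_from_levels(levels, n_levels=GLCM_LEVELS):
    # midpoints of the quantization bins map back to the same level
    return (levels + 0.5) / n_levels


class TestGLCM:
    def test_constant_image(self):
        out = glcm_features(np.full((16, 16), 0.4))
        assert out["glcm_contrast"] == 0.0
        assert out["glcm_energy"] == 1.0
        assert out["glcm_homogeneity"] == 1.0
        assert out["glcm_entropy"] == 0.0
        assert out["glcm_correlation"] == 0.0  # undefined -> defined as 0

    def test_checkerboard_closed_form(self):
        # levels alternate {0, L-1}: every horizontal pair differs by L-1
        levels = np.indices((4, 4)).sum(axis=0) % 2 * (GLCM_LEVELS - 1)
        img = _img_from_levels(levels)
        out = glcm_features(img)
        assert out["glcm_contrast_a0"] == pytest.approx((GLCM_LEVELS - 1) ** 2)
        # brute-force pair counting: symmetric GLCM has two off-diagonal
        # entries of mass 0.5 each -> energy 0.5
        assert out["glcm_energy_a0"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        levels = _levels_image(rng)
        img = _img_from_levels(levels)
        mats = glcm_matrix(img)
        out = glcm_features(img)
        per_offset = []
        for k, name in enumerate(GLCM_OFFSETS):
            oracle_mat = brute_glcm(levels, GLCM_OFFSETS[name], GLCM_LEVELS)
            np.testing.assert_allclose(mats[:, :, k], oracle_mat, atol=1e-10)
            props = brute_glcm_props(oracle_mat)
            per_offset.append(props)
            for f in ("contrast", "correlation", "energy", "homogeneity"):
                assert out[f"glcm_{f}_a{name}"] == pytest.approx(props[f], abs=1e-10)
        for f in PROPS:
            avg = np.mean([p[f] for p in per_offset])
            assert out[f"glcm_{f}"] == pytest.approx(avg, abs=1e-10)

    def test_offset_average_invariant_under_rot90(self):
        rng = np.random.default_rng(11)
        img = rng.random((32, 32))
        a = glcm_features(img)
        b = glcm_features(np.rot90(img))
        for f in PROPS:
            assert a[f"glcm_{f}"] == pytest.approx(b[f"glcm_{f}"], abs=1e-10)


class TestLBP:
    def test_constant_image_all_mass_in_flat_bin(self):
        out = lbp_features(np.full((16, 16), 0.3))
        assert out["lbp_u8"] == pytest.approx(1.0)

    def test_histogram_sums_to_one(self):
        rng = np.random.default_rng(1)
        out = lbp_features(rng.random((24, 24)))
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_hand_coded_5x5(self):
        img = np.array([
            [0.0, 0.2, 0.4, 0.6, 0.8],
            [0.8, 0.6, 0.4, 0.2, 0.0],
            [0.0, 0.0, 1.0, 0.0, 0.0],
            [0.2, 0.8, 0.2, 0.8, 0.2],
            [1.0, 1.0, 1.0, 0.0, 0.0],
        ])
        out = lbp_features(img)
        oracle = brute_lbp_uniform_hist(np.asarray(quantize(img, 256), dtype=float))
        got = np.array([out[f"lbp_u{b}"] for b in range(9)] + [out["lbp_nonuniform"]])
        np.testing.assert_allclose(got, oracle, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        # well-separated gray levels avoid interpolation ties at the border
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 8, size=(8, 8)) / 8.0
        out = lbp_features(img)
        oracle = brute_lbp_uniform_hist(np.asarray(quantize(img, 256), dtype=float))
        got = np.array([out[f"lbp_u{b}"] for b in range(9)] + [out["lbp_nonuniform"]])
        np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_flip_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 16, size=(20, 20)) / 16.0
        a = lbp_features(img)
        b = lbp_features(img[::-1].copy())
        c = lbp_features(img[:, ::-1].copy())
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-12)
            assert a[key] == pytest.approx(c[key], abs=1e-12)


class TestGabor:
    def test_constant_image_zero_response(self):
        out = gabor_features(np.full((64, 64), 0.7))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())

    def test_grating_peaks_at_matching_filter(self):
        # vertical grating at bank frequency 0.2 varies along x (theta = 0)
        x = np.arange(96)
        img = np.tile(0.5 + 0.4 * np.sin(2 * np.pi * 0.2 * x), (96, 1))
        out = gabor_features(img)
        means = {k: v for k, v in out.items() if k.endswith("_mean")}
        assert max(means, key=means.get) == "gabor_f0.2_o0_mean"

    def test_white_noise_orientation_symmetry(self):
        rng = np.random.default_rng(123)
        img = rng.random((128, 128))
        out = gabor_features(img)
        for freq in ("0.1", "0.2", "0.4"):
            vals = [out[f"gabor_f{freq}_o{o}_mean"] for o in ("0", "45", "90", "135")]
            assert (max(vals) - min(vals)) / np.mean(vals) < 0.10


class TestTamura:
    def test_constant_image(self):
        out = tamura_features(np.full((64, 64), 0.5))
        assert np.isfinite(out["tamura_coarseness"])
        assert out["tamura_contrast"] == 0.0
        assert out["tamura_directionality"] == 0.0

    def test_stripes_more_directional_than_noise(self):
        x = np.arange(64)
        stripes = np.tile(0.5 + 0.5 * np.sin(2 * np.pi * x / 8), (64, 1))
        rng = np.random.default_rng(0)
        noise = rng.random((64, 64))
        assert (tamura_features(stripes)["tamura_directionality"]
                > tamura_features(noise)["tamura_directionality"])

    def test_coarse_blobs_coarser_than_fine_noise(self):
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((96, 96))
        blobs = gaussian_filter(raw, 8)
        blobs = (blobs - blobs.min()) / (blobs.max() - blobs.min())
        fine = rng.random((96, 96))
        assert (tamura_features(blobs)["tamura_coarseness"]
                > tamura_features(fine)["tamura_coarseness"])


class TestHistogramFamilies:
    def test_constant_image(self):
        out = histogram_features(np.full((32, 32), 0.25))
        assert out["hist_variance"] == 0.0
        assert out["hist_entropy"] == 0.0
        assert out["hist_energy"] == 1.0
        assert out["hist_skewness"] == 0.0 and out["hist_kurtosis"] == 0.0

    def test_two_level_closed_form(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        out = histogram_features(img)
        assert out["hist_mean"] == pytest.approx(0.5)
        assert out["hist_variance"] == pytest.approx(0.25)
        assert out["pct_50"] == pytest.approx(0.5)

    def test_entropy_bounded_by_log_bins(self):
        rng = np.random.default_rng(4)
        out = histogram_features(rng.random((64, 64)))
        assert out["hist_entropy"] <= np.log2(32) + 1e-12
        assert out["grad_entropy"] <= np.log2(32) + 1e-12


class TestRegistryAndFiltering:
    def test_registry_has_80_unique_features(self):
        reg = FeatureRegistry.default()
        assert len(reg) == 80
        assert len(set(reg.names)) == 80
        assert set(reg.families) == {"GLCM", "Gabor", "LBP", "Tamura",
                                     "lower_histogram", "higher_histogram"}

    def test_extraction_deterministic_and_finite(self):
        rng = np.random.default_rng(5)
        img = rng.random((224, 224))
        a = extract_features(img)
        b = extract_features(img)
        np.testing.assert_array_equal(a, b)
        assert np.isfinite(a).all()

    def test_zero_and_duplicate_columns_dropped(self):
        reg = FeatureRegistry.default()
        rng = np.random.default_rng(6)
        X = rng.random((20, 80))
        X[:, 3] = 0.0
        X[:, 10] = X[:, 2]  # duplicate of an earlier column
        X[:, 7] = np.nan
        retained = filter_features(X, reg)
        assert not retained[3] and not retained[10] and not retained[7]
        assert retained[2]
        assert retained.sum() == 77

    def test_engineered_80_to_55(self):
        # 25 degenerate columns among 80: 10 zero, 5 NA, 10 duplicates
        reg = FeatureRegistry.default()
        rng = np.random.default_rng(7)
        X = rng.random((30, 80))
        X[:, :10] = 0.0
        X[:, 10:15] = np.nan
        for j in range(15, 25):
            X[:, j] = X[:, j + 30]  # duplicates later columns; first kept wins
        retained = filter_features(X, reg)
        assert retained.sum() == 55
        assert reg.retained_names == tuple(np.array(reg.names)[retained])

    def test_all_degenerate_is_error(self):
        reg = FeatureRegistry.default()
        with pytest.raises(ValueError, match="every column"):
            filter_features(np.zeros((5, 80)), reg)


def test_full_vector_flip_invariant_families():
    rng = np.random.default_rng(8)
    img = rng.integers(0, 32, size=(64, 64)) / 32.0
    reg = FeatureRegistry.default()
    a = extract_features(img, reg)
    b = extract_features(img[:, ::-1].copy(), reg)
    n_interior = 62 * 62
    for i, (name, fam) in enumerate(zip(reg.names, reg.families)):
        if fam in ("lower_histogram", "higher_histogram"):
            assert a[i] == pytest.approx(b[i], abs=1e-9), name
        elif fam == "LBP":
            # exact up to interpolation ties, which may flip the odd pixel
            assert a[i] == pytest.approx(b[i], abs=2 / n_interior), name
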