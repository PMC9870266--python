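import numpy as np
import pytest

from btfsc.features import (
    DEFAULT_OFFSETS,
    FEATURE_NAMES,
    GAOMFeatureSelector,
    GASettings,
    GLCMMatrix,
    band_features,
    color_stats,
    compute_glcm,
    gaom_select,
    glcm_features,
    hybrid_features,
    irdwt2,
    quantize,
    rdwt2,
)


def glcm_oracle(img, mask, levels, offsets, symmetric=True):
    """Brute-force double-loop pair enumeration."""
    q = quantize(img, levels)
    h, w = q.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    counts = np.zeros((levels, levels))
    for dr, dc in offsets:
        for i in range(h):
            for j in range(w):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < h and 0 <= j2 < w and mask[i, j] and mask[i2, j2]:
                    counts[q[i, j], q[i2, j2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


class TestGLCM:
    def test_two_row_example(self):
        img = np.array([[0.0, 0.0], [0.9, 0.9]])
        g = compute_glcm(img, levels=2, offsets=[(0, 1)])
        assert np.allclose(g.S, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_entry(self):
        g = compute_glcm(np.full((8, 8), 0.5), levels=4)
        q = 2  # 0.5 * 4 = bin 2
        expected = np.zeros((4, 4))
        expected[q, q] = 1.0
        assert np.allclose(g.S, expected)

    @pytest.mark.parametrize("masked", [False, True])
    def test_matches_bruteforce_oracle(self, rng, masked):
        img = rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.3) if masked else None
        g = compute_glcm(img, mask=mask, levels=8)
        oracle = glcm_oracle(img, mask, 8, DEFAULT_OFFSETS)
        assert np.abs(g.S - oracle).max() <= 1e-12

    def test_too_few_pairs_rejected(self):
        mask = np.zeros((8, 8), dtype=np.int64)
        mask[0, 0] = 1
        with pytest.raises(ValueError, match="pairs"):
            compute_glcm(np.zeros((8, 8)), mask=mask)


class TestGLCMFeatures:
    def test_diagonal_half_half_matrix(self):
        g = GLCMMatrix(
            S=np.array([[0.5, 0.0], [0.0, 0.5]]), levels=2, offsets=((0, 1),)
        )
        contrast, homog, corr, asm, energy = glcm_features(g)
        assert contrast == 0.0
        assert homog == 1.0
        assert corr == pytest.approx(1.0)
        assert asm == pytest.approx(0.5)
        assert energy == pytest.approx(np.sqrt(0.5))

    def test_constant_image_features(self):
        g = compute_glcm(np.full((8, 8), 0.3), levels=4)
        contrast, homog, corr, asm, energy = glcm_features(g)
        assert (contrast, homog, asm, energy) == (0.0, 1.0, 1.0, 1.0)
        assert corr == 1.0  # degenerate marginals convention

    def test_energy_is_sqrt_of_asm(self):
        S = np.full((2, 2), 0.25)
        g = GLCMMatrix(S=S, levels=2, offsets=((0, 1),))
        *_, asm, energy = glcm_features(g)
        assert asm == pytest.approx(0.25)
        assert energy == pytest.approx(0.5)

    def test_bounds(self, rng):
        g = compute_glcm(rng.random((16, 16)), levels=8)
        _, homog, _, asm, energy = glcm_features(g)
        assert 0.0 < homog <= 1.0
        assert 0.0 < asm <= 1.0
        assert energy >= asm


class TestRDWT:
    def test_constant_image_has_zero_detail_bands(self):
        bands = rdwt2(np.full((16, 16), 0.7))
        for name in ("LH1", "HL1", "HH1", "LH2", "HL2", "HH2"):
            assert np.abs(getattr(bands, name)).max() < 1e-12

    def test_perfect_reconstruction(self, rng):
        img = rng.random((32, 32))
        assert np.abs(irdwt2(rdwt2(img)) - img).max() <= 1e-8

    def test_band_energies_are_shift_invariant(self, rng):
        img = rng.random((32, 32))
        shifted = np.roll(img, (1, 1), axis=(0, 1))
        a = rdwt2(img)
        b = rdwt2(shifted)
        for name in ("LL1", "LH1", "HL1", "HH1", "LL2", "LH2", "HL2", "HH2"):
            ea = np.mean(getattr(a, name) ** 2)
            eb = np.mean(getattr(b, name) ** 2)
            assert abs(ea - eb) <= 1e-8

    def test_unsupported_wavelet_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            rdwt2(np.zeros((16, 16)), wavelet="nosuch9")

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            rdwt2(np.zeros((18, 18)))


class TestBandFeatures:
    def test_zero_band(self):
        ref = np.random.default_rng(0).random((8, 8))
        assert band_features(np.zeros((8, 8)), ref) == (0.0, 0.0, 0.0)

    def test_band_equal_to_reference_has_unit_correlation(self, rng):
        x = rng.random((8, 8))
        *_, corr = band_features(x, x)
        assert corr == pytest.approx(1.0)

    def test_uniform_histogram_entropy_is_eight_bits(self):
        band = np.repeat(np.arange(256) / 255.0, 4).reshape(32, 32)
        _, entropy, _ = band_features(band, band)
        assert entropy == pytest.approx(8.0)


class TestColorStats:
    def test_constant_region(self):
        img = np.full((8, 8), 0.3)
        assert color_stats(img, np.ones((8, 8))) == (pytest.approx(0.3), 0.0)

    def test_four_value_example(self):
        img = np.zeros((8, 8))
        mask = np.zeros((8, 8), dtype=np.int64)
        img[0, :4] = [0.0, 1.0, 1.0, 0.0]
        mask[0, :4] = 1
        mean, std = color_stats(img, mask)
        assert (mean, std) == (0.5, 0.5)

    def test_matches_two_pass_oracle(self, rng):
        img = rng.random((16, 16))
        mask = np.ones((16, 16), dtype=np.int64)
        mean, std = color_stats(img, mask)
        mu = img.sum() / img.size
        sd = np.sqrt(((img - mu) ** 2).sum() / img.size)
        assert abs(mean - mu) < 1e-12 and abs(std - sd) < 1e-12

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            color_stats(np.zeros((8, 8)), np.zeros((8, 8)))


class TestHybridVector:
    def test_schema_length_and_determinism(self, clean_benign):
        from btfsc.fusion import fuse

        fused = fuse(clean_benign.mri, clean_benign.ct)
        v1 = hybrid_features(fused, clean_benign.mask)
        v2 = hybrid_features(fused, clean_benign.mask)
        assert v1.shape == (13,) and len(FEATURE_NAMES) == 13
        assert np.array_equal(v1, v2)

    def test_malignant_texture_raises_glcm_contrast(self):
        from btfsc.fusion import fuse
        from btfsc.phantom import PhantomSpec, generate_phantom_pair

        wins = 0
        n = 10
        for seed in range(n):
            vals = {}
            for label in ("benign", "malignant"):
                s = generate_phantom_pair(
                    PhantomSpec(seed=seed, noise_sigma=0.0, class_label=label)
                )
                fused = fuse(s.mri, s.ct)
                vals[label] = hybrid_features(fused, s.mask)[0]
            wins += vals["malignant"] > vals["benign"]
        assert wins >= 0.9 * n


class TestGAOM:
    @staticmethod
    def separable_problem(n=100, d=10, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array(["a", "b"] * (n // 2))
        F = rng.normal(0, 1, size=(n, d))
        F[:, 0] = (y == "b") * 4.0 + rng.normal(0, 0.2, n)
        return F, y

    def test_separating_feature_is_selected(self):
        F, y = self.separable_problem()
        idx = gaom_select(F, y, seed=1)
        assert 0 in idx

    def test_identical_features_yield_minimal_subset(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 1, 40)
        F = np.tile(col[:, None], (1, 6))
        y = np.array(["a", "b"] * 20)
        idx = gaom_select(F, y, seed=0)
        assert len(idx) == 1

    def test_deterministic_under_seed(self):
        F, y = self.separable_problem(seed=3)
        assert np.array_equal(gaom_select(F, y, seed=7), gaom_select(F, y, seed=7))

    def test_single_class_rejected(self):
        F = np.random.default_rng(0).random((20, 4))
        with pytest.raises(ValueError, match="class"):
            gaom_select(F, np.array(["a"] * 20))

    def test_never_empty_and_selector_api(self):
        F, y = self.separable_problem(seed=5)
        sel = GAOMFeatureSelector(seed=2).fit(F, y)
        assert sel.get_support().sum() >= 1
        assert sel.transform(F).shape[1] == sel.get_support().sum()
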