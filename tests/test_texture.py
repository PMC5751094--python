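import numpy as np
import pytest

from planktovision.features import (
    DEFAULT_LAGS,
    GaborBank,
    bgc1_code_image,
    bgc1_features,
    gabor_features,
    lbp_code_image,
    lbp_features,
    variogram_directional,
    variogram_features,
)

# ring order shared by the LBP/BGC oracles: clockwise from top-left, MSB first
RING = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


class TestGabor:
    def test_bank_has_48_filters(self):
        assert len(GaborBank()) == 48

    def test_vector_length_96(self):
        img = np.random.default_rng(0).integers(0, 255, (40, 40)).astype(float)
        assert len(gabor_features(img)) == 96

    def test_zero_image_gives_zero_features(self):
        vals = gabor_features(np.zeros((32, 32))).values
        assert np.allclose(vals, 0.0, atol=1e-6)

    def test_impulse_mean_matches_direct_convolution(self):
        """Mean |response| to a centered unit impulse equals Σ|g|/(m·n),
        cross-checked with an explicit double-loop convolution."""
        bank = GaborBank()
        kernel = bank.kernels[0]  # highest frequency -> small support
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        # direct double-loop convolution, 'same' cropping
        kh, kw = kernel.shape
        full = np.zeros((15 + kh - 1, 15 + kw - 1), dtype=complex)
        for r in range(15):
            for c in range(15):
                if img[r, c]:
                    full[r : r + kh, c : c + kw] += img[r, c] * kernel
        r0, c0 = (kh - 1) // 2, (kw - 1) // 2
        direct_mag = np.abs(full[r0 : r0 + 15, c0 : c0 + 15])
        fv = gabor_features(img, bank)
        assert fv.values[0] == pytest.approx(direct_mag.mean(), rel=1e-9)
        assert fv.values[1] == pytest.approx(direct_mag.std(), rel=1e-9)


class TestVariogram:
    def test_constant_image_gives_zero(self):
        vals = variogram_features(np.full((24, 24), 9.0)).values
        assert np.allclose(vals, 0.0)

    def test_horizontal_ramp_closed_form(self):
        """For I(x,y) = x the directional variogram at lag h is h²/2."""
        img = np.tile(np.arange(20.0), (20, 1))
        for h in (1, 3, 5):
            assert variogram_directional(img, (0, h)) == pytest.approx(h * h / 2)

    def test_matches_brute_force_pair_sum(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16)) * 255
        h = 3
        expected = []
        for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1)):
            off = (dr * h, dc * h)
            acc, cnt = 0.0, 0
            for r in range(16):
                for c in range(16):
                    rr, cc = r + off[0], c + off[1]
                    if 0 <= rr < 16 and 0 <= cc < 16:
                        acc += (img[r, c] - img[rr, cc]) ** 2
                        cnt += 1
            expected.append(acc / (2 * cnt))
        fv = variogram_features(img, lags=(3,))
        assert fv.values[0] == pytest.approx(np.mean(expected), rel=1e-9)

    def test_oversized_lag_raises(self):
        with pytest.raises(ValueError):
            variogram_directional(np.zeros((8, 8)), (0, 9))

    def test_default_lag_roster(self):
        img = np.random.default_rng(2).random((40, 40))
        assert len(variogram_features(img)) == len(DEFAULT_LAGS)


def _oracle_code(patch, bgc=False):
    """Hand enumeration of the 8 ring bits for a 3×3 patch."""
    center = patch[1, 1]
    nb = [patch[1 + dr, 1 + dc] for dr, dc in RING]
    if not bgc:
        bits = [1 if v >= center else 0 for v in nb]
    else:
        bits = [1 if nb[k] - nb[(k + 1) % 8] >= 0 else 0 for k in range(8)]
    code = sum(b << (7 - i) for i, b in enumerate(bits))
    return code - 1 if bgc else code


class TestLBP:
    def test_constant_image_codes_255(self):
        codes = lbp_code_image(np.full((6, 6), 7.0))
        assert np.all(codes == 255)
        fv = lbp_features(np.full((12, 12), 7.0), grid=1)
        assert fv.values[255] == 100  # 10×10 interior pixels
        assert fv.values.sum() == 100

    def test_cell_totals_equal_interior_pixels(self):
        img = np.random.default_rng(3).integers(0, 255, (24, 24)).astype(float)
        fv = lbp_features(img, grid=4)
        per_cell = fv.values.reshape(16, 256).sum(axis=1)
        assert np.all(per_cell == 16)  # each 6×6 cell has a 4×4 interior

    def test_hand_coded_5x5(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 255, (5, 5)).astype(float)
        expected = np.zeros(256)
        for r in range(1, 4):
            for c in range(1, 4):
                expected[_oracle_code(img[r - 1 : r + 2, c - 1 : c + 2])] += 1
        fv = lbp_features(img, grid=1)
        assert np.array_equal(fv.values, expected)

    def test_invariant_under_monotone_remap(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 255, (20, 20)).astype(float)
        lut = np.cumsum(rng.uniform(0.5, 2.0, 256))  # strictly increasing
        remapped = lut[img.astype(int)]
        assert np.array_equal(
            lbp_features(img, grid=2).values, lbp_features(remapped, grid=2).values
        )


class TestBGC1:
    def test_constant_patch_codes_254(self):
        codes = bgc1_code_image(np.full((5, 5), 3.0))
        assert np.all(codes == 254)

    def test_explicit_patch_matches_bit_enumeration(self):
        patch = np.array([[1, 2, 3], [8, 0, 4], [7, 6, 5]], dtype=float)
        assert bgc1_code_image(patch)[0, 0] == _oracle_code(patch, bgc=True)

    def test_random_image_matches_oracle(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 255, (7, 7)).astype(float)
        codes = bgc1_code_image(img)
        for r in range(1, 6):
            for c in range(1, 6):
                assert codes[r - 1, c - 1] == _oracle_code(img[r - 1 : r + 2, c - 1 : c + 2], bgc=True)

    def test_histogram_normalized(self):
        img = np.random.default_rng(7).integers(0, 255, (15, 15)).astype(float)
        fv = bgc1_features(img)
        assert len(fv) == 255
        assert fv.values.sum() == pytest.approx(1.0)

    def test_invariant_under_monotone_remap(self):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 255, (18, 18)).astype(float)
        lut = np.cumsum(rng.uniform(0.5, 2.0, 256))
        assert np.allclose(
            bgc1_features(img).values, bgc1_features(lut[img.astype(int)]).values
        )
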