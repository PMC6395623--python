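"""Spectrum computation, noise cutoff and thresholding.

The brute-force oracles here (O(N^4) DFT summation, exhaustive corner scans,
per-entry threshold counts) are independent of the vectorised implementation
they check.
"""

import numpy as np
import pytest

from fibralign import GrayImage
from fibralign.directionality import (
    SpectrumDistribution,
    apply_cutoff,
    compute_spectrum,
    estimate_noise_cutoff,
    log_display_normalize,
)
from fibralign.errors import (DegenerateSpectrumError, ImageInputError,
                              ParameterError)


def dft_modulus_bruteforce(pixels):
    """O(N^4) direct DFT-modulus summation, recentred like fftshift."""
    n_r, n_c = pixels.shape
    out = np.zeros((n_r, n_c))
    for k in range(n_r):
        for l in range(n_c):
            acc = 0.0 + 0.0j
            for r in range(n_r):
                for c in range(n_c):
                    acc += pixels[r, c] * np.exp(
                        -2j * np.pi * (k * r / n_r + l * c / n_c))
            out[k, l] = abs(acc)
    return np.fft.fftshift(out)


class TestComputeSpectrum:
    def test_constant_image_has_all_mass_at_dc(self, gray_from_array):
        c, n = 0.37, 9
        spec = compute_spectrum(gray_from_array(np.full((n, n), c)))
        assert spec.modulus[spec.center] == pytest.approx(c * n * n)
        off = spec.modulus.copy()
        off[spec.center] = 0.0
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_modulus_point_symmetric_for_real_images(self, rng,
                                                     gray_from_array):
        spec = compute_spectrum(gray_from_array(rng.uniform(size=(17, 17))))
        np.testing.assert_allclose(spec.modulus,
                                   spec.modulus[::-1, ::-1],
                                   rtol=1e-8, atol=1e-10)

    def test_cosine_matches_bruteforce_dft(self, gray_from_array):
        n = 9
        x = np.arange(n)
        img = 0.5 + 0.4 * np.cos(2 * np.pi * 2 * x / n)  # 2 cycles along x
        pixels = np.tile(img, (n, 1))
        spec = compute_spectrum(gray_from_array(pixels))
        np.testing.assert_allclose(spec.modulus,
                                   dft_modulus_bruteforce(pixels),
                                   rtol=1e-8, atol=1e-8)
        # off-DC mass sits on the horizontal frequency axis (central row)
        mod = spec.modulus.copy()
        mod[spec.center] = 0.0
        central_row_mass = mod[spec.center[0], :].sum()
        assert central_row_mass == pytest.approx(mod.sum(), rel=1e-9)

    def test_random_image_matches_bruteforce_dft(self, rng, gray_from_array):
        pixels = rng.uniform(size=(8, 8))  # even size exercised too
        spec = compute_spectrum(gray_from_array(pixels))
        np.testing.assert_allclose(spec.modulus,
                                   dft_modulus_bruteforce(pixels),
                                   rtol=1e-8, atol=1e-8)

    def test_nonfinite_pixels_rejected(self):
        img = GrayImage.__new__(GrayImage)  # bypass validation on purpose
        object.__setattr__(img, "pixels", np.full((4, 4), np.inf))
        object.__setattr__(img, "source_id", "inf")
        with pytest.raises(ImageInputError):
            compute_spectrum(img)

    def test_unknown_window_rejected(self, gray_from_array):
        with pytest.raises(ParameterError):
            compute_spectrum(gray_from_array(np.ones((8, 8))), window="hamming")


class TestNoiseCutoff:
    def corner_max_bruteforce(self, mod, c):
        h, w = mod.shape
        vals = []
        for r in range(h):
            for col in range(w):
                if (r < c or r >= h - c) and (col < c or col >= w - c):
                    vals.append(mod[r, col])
        return max(vals)

    def test_matches_exhaustive_corner_scan(self, rng):
        mod = rng.uniform(0, 10, size=(31, 27))
        spec = SpectrumDistribution(modulus=mod)
        for c in (3, 5, 9):
            assert estimate_noise_cutoff(spec, corner_px=c) == pytest.approx(
                self.corner_max_bruteforce(mod, c), rel=1e-12)

    def test_planted_corner_value_is_found(self, rng):
        mod = rng.uniform(0, 1, size=(41, 41))
        mod[39, 2] = 7.5  # inside the bottom-left 5x5 corner block
        cutoff = estimate_noise_cutoff(SpectrumDistribution(modulus=mod),
                                       corner_px=5)
        assert cutoff == 7.5

    def test_zero_corners_and_constant_field(self):
        mod = np.ones((21, 21))
        assert estimate_noise_cutoff(SpectrumDistribution(modulus=mod),
                                     corner_px=4) == 1.0
        mod2 = np.ones((21, 21))
        for sl in (np.s_[:4, :4], np.s_[:4, -4:], np.s_[-4:, :4],
                   np.s_[-4:, -4:]):
            mod2[sl] = 0.0
        assert estimate_noise_cutoff(SpectrumDistribution(modulus=mod2),
                                     corner_px=4) == 0.0

    def test_overlapping_corner_blocks_rejected(self):
        spec = SpectrumDistribution(modulus=np.ones((21, 21)))
        with pytest.raises(ParameterError):
            estimate_noise_cutoff(spec, corner_px=10)


class TestApplyCutoff:
    def test_zero_cutoff_without_dc_exclusion_is_identity(self, rng):
        mod = rng.uniform(0.1, 1, size=(9, 9))
        spec = SpectrumDistribution(modulus=mod)
        out = apply_cutoff(spec, 0.0, exclude_dc=False)
        np.testing.assert_array_equal(out.modulus, mod)

    def test_threshold_matches_bruteforce_survivor_count(self, rng):
        mod = rng.uniform(0, 4, size=(13, 13))
        mod.ravel()[:4] = [1.0, 2.0, 3.0, 4.0]
        cutoff = 2.5
        out = apply_cutoff(SpectrumDistribution(modulus=mod), cutoff,
                           exclude_dc=False)
        survivors = int((out.modulus > 0).sum())
        expected = sum(1 for v in mod.ravel() if v >= cutoff and v > 0)
        assert survivors == expected
        assert np.all((out.modulus >= cutoff) | (out.modulus == 0.0))

    def test_constant_image_spectrum_degenerates_when_dc_excluded(
            self, gray_from_array):
        spec = compute_spectrum(gray_from_array(np.full((9, 9), 0.5)))
        with pytest.raises(DegenerateSpectrumError):
            apply_cutoff(spec, 1e-6, exclude_dc=True)


class TestLogDisplayNormalize:
    def test_constant_spectrum_maps_to_zeros(self):
        out = log_display_normalize(SpectrumDistribution(np.full((5, 5), 3.0)))
        np.testing.assert_array_equal(out, 0.0)

    def test_two_point_range_spans_unit_interval(self):
        mod = np.array([[0.0, np.e - 1.0]])
        out = log_display_normalize(SpectrumDistribution(mod))
        np.testing.assert_allclose(out, [[0.0, 1.0]])

    def test_rank_order_preserved(self, rng):
        mod = rng.uniform(0, 100, size=(8, 8))
        out = log_display_normalize(SpectrumDistribution(mod))
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_array_equal(np.argsort(out.ravel()),
                                      np.argsort(mod.ravel()))
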