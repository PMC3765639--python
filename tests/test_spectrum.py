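"""Windowing, normalised DFT amplitude spectra, blob binarisation and
moment-equivalent ellipse measurement."""

import numpy as np
import pytest

from gaborient.spectrum import (
    AmplitudeSpectrum,
    DegenerateSpectrumError,
    amplitude_spectrum,
    binarize_spectrum,
    equivalent_ellipse,
    hann2d,
)


def _dft_oracle(img):
    """Direct double-sum DFT modulus with the 1/(MN) prefactor, centred."""
    m, n = img.shape
    out = np.zeros((m, n), dtype=complex)
    xs = np.arange(m)
    ys = np.arange(n)
    for u in range(m):
        for v in range(n):
            phase = np.exp(
                -2j * np.pi * (u * xs[:, None] / m + v * ys[None, :] / n)
            )
            out[u, v] = np.sum(img * phase) / (m * n)
    return np.fft.fftshift(np.abs(out))


class TestHann2d:
    def test_corners_are_zero(self, rng):
        out = hann2d(rng.random((20, 24)))
        assert out[0, 0] == out[0, -1] == out[-1, 0] == out[-1, -1] == 0.0

    def test_odd_size_center_preserved(self):
        out = hann2d(np.ones((21, 21)))
        assert out[10, 10] == pytest.approx(1.0)

    def test_separable_outer_product(self, rng):
        img = rng.random((18, 22))
        w = np.outer(np.hanning(18), np.hanning(22))
        assert np.allclose(hann2d(img), img * w)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            hann2d(np.ones((8, 8)))


class TestAmplitudeSpectrum:
    def test_constant_image_concentrates_at_dc(self):
        spec = amplitude_spectrum(np.full((32, 32), 5.0))
        center = spec.center
        assert spec.values[center] == pytest.approx(5.0)
        off_dc = spec.values.copy()
        off_dc[center] = 0.0
        assert np.abs(off_dc).max() < 1e-12

    def test_bin_aligned_cosine_two_half_amplitude_bins(self):
        x = np.arange(64)
        img = np.tile(np.cos(2 * np.pi * (4 / 64) * x), (64, 1))
        spec = amplitude_spectrum(img)
        cy, cx = spec.center
        assert spec.values[cy, cx + 4] == pytest.approx(0.5)
        assert spec.values[cy, cx - 4] == pytest.approx(0.5)
        rest = spec.values.copy()
        rest[cy, cx + 4] = rest[cy, cx - 4] = 0.0
        assert rest.max() < 1e-12

    def test_matches_direct_double_sum_oracle(self, rng):
        img = rng.normal(size=(8, 8))
        spec = amplitude_spectrum(img)
        assert np.abs(spec.values - _dft_oracle(img)).max() < 1e-10

    def test_parseval_under_normalisation(self, rng):
        img = rng.normal(size=(24, 17))
        spec = amplitude_spectrum(img)
        lhs = np.sum(spec.values**2)
        rhs = np.sum(img**2) / img.size
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_translation_invariance(self, rng):
        img = rng.normal(size=(32, 32))
        a = amplitude_spectrum(img).values
        b = amplitude_spectrum(np.roll(img, (5, -3), axis=(0, 1))).values
        assert np.allclose(a, b, atol=1e-12)

    def test_non_finite_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.inf
        with pytest.raises(ValueError):
            amplitude_spectrum(img)


class TestBinarizeSpectrum:
    def _spec_from(self, values):
        return AmplitudeSpectrum(values=np.asarray(values, dtype=float))

    def test_single_central_peak_survives(self):
        values = np.zeros((31, 31))
        values[15, 15] = 10.0
        mask = binarize_spectrum(self._spec_from(values), quantile=0.9)
        assert mask[15, 15] and mask.sum() == 1

    def test_central_component_beats_larger_peripheral_blob(self):
        values = np.zeros((41, 41))
        values[19:22, 19:22] = 5.0  # 3x3 blob containing DC (20, 20)
        values[2:7, 2:7] = 5.0  # larger 5x5 blob away from DC
        mask = binarize_spectrum(self._spec_from(values), quantile=0.9)
        assert mask[20, 20]
        assert mask.sum() == 9

    def test_largest_component_when_dc_below_threshold(self):
        values = np.zeros((41, 41))
        values[2:7, 2:7] = 5.0
        values[30:32, 30:32] = 5.0
        mask = binarize_spectrum(self._spec_from(values), quantile=0.97)
        assert not mask[20, 20]
        assert mask.sum() == 25

    def test_select_all_keeps_whole_scatter_pattern(self):
        values = np.zeros((41, 41))
        values[2:7, 2:7] = 5.0
        values[30:32, 30:32] = 5.0
        mask = binarize_spectrum(self._spec_from(values), quantile=0.97,
                                 select="all")
        assert mask.sum() == 29

    def test_anisotropic_gaussian_level_set_ratio(self):
        u, v = np.meshgrid(np.arange(101) - 50, np.arange(101) - 50,
                           indexing="xy")
        values = np.exp(-(u**2 / (2 * 8.0**2) + v**2 / (2 * 2.0**2)))
        mask = binarize_spectrum(self._spec_from(values), quantile=0.95)
        e = equivalent_ellipse(mask)
        assert e.long_axis / e.short_axis == pytest.approx(4.0, rel=0.10)

    def test_quantile_bounds_enforced(self):
        values = np.ones((20, 20))
        for q in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                binarize_spectrum(self._spec_from(values), quantile=q)

    def test_unreachable_threshold_is_degenerate(self):
        values = np.ones((20, 20))
        with pytest.raises(DegenerateSpectrumError):
            binarize_spectrum(self._spec_from(values), quantile=0.5,
                              threshold=np.inf)


class TestEquivalentEllipse:
    def test_disk_is_round(self):
        y, x = np.mgrid[-15:16, -15:16]
        mask = x**2 + y**2 <= 10**2
        e = equivalent_ellipse(mask)
        assert e.long_axis / e.short_axis == pytest.approx(1.0, rel=0.02)

    def test_rectangle_axis_ratio_and_orientation(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[10:20, 10:50] = True  # 40 wide (x), 10 tall (y)
        e = equivalent_ellipse(mask)
        # Second moments of a 40x10 discrete rectangle: variances
        # (w^2-1)/12 and (h^2-1)/12, so the axis ratio approaches 4.
        coords = np.argwhere(mask).astype(float)
        var_x = coords[:, 1].var()
        var_y = coords[:, 0].var()
        expected = np.sqrt(var_x / var_y)
        assert e.long_axis / e.short_axis == pytest.approx(expected, rel=1e-9)
        assert e.long_axis / e.short_axis == pytest.approx(4.0, rel=0.02)
        assert e.orientation_deg == pytest.approx(0.0, abs=1e-6)

    def test_single_bin_degenerate_axes(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 7] = True
        e = equivalent_ellipse(mask)
        assert e.long_axis == e.short_axis == 1.0

    def test_transpose_preserves_axes_and_swaps_orientation(self, rng):
        mask = rng.random((40, 40)) > 0.8
        mask[20, 20] = True
        a = equivalent_ellipse(mask)
        b = equivalent_ellipse(mask.T)
        assert b.long_axis == pytest.approx(a.long_axis)
        assert b.short_axis == pytest.approx(a.short_axis)

    def test_scale_invariant_axis_ratio(self):
        def disk(r, size):
            y, x = np.mgrid[-size:size + 1, -size:size + 1]
            return x**2 + y**2 <= r**2

        small = equivalent_ellipse(disk(8, 12))
        large = equivalent_ellipse(disk(24, 30))
        assert small.long_axis / small.short_axis == pytest.approx(
            large.long_axis / large.short_axis, rel=0.02
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            equivalent_ellipse(np.zeros((10, 10), dtype=bool))
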