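"""Raman pipeline: smoothing, baseline, cropping, peak fits, band ratios."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from weldtherm import raman as rm

# Table of printed per-sample peak parameters used as fixture inputs:
# (weld time s, amide-III height, reference-band height)
PRINTED_INTENSITIES = {
    15.0: [(3227.29, 1409.34), (3220.33, 1433.47), (3038.43, 1297.59)],
    25.0: [(1704.50, 888.80), (2165.38, 1223.91), (2669.64, 1511.89), (1464.48, 775.89)],
    30.0: [
        (3484.08, 5100.98),
        (1086.55, 1502.61),
        (422.15, 634.66),
        (3203.23, 3251.95),
        (1869.72, 1999.29),
    ],
}


def flat_spectrum(lo=800.0, hi=2000.0, step=1.0, value=0.0):
    w = np.arange(lo, hi + step / 2, step)
    return rm.RamanSpectrum(w, np.full(w.size, value))


def peak_result(height, center=1247.0):
    return rm.PeakFitResult(center=center, height=height, fwhm=40.0, eta=0.5, residual=0.0)


class TestSmooth:
    def test_constant_unchanged(self):
        s = flat_spectrum(value=5.0)
        out = rm.smooth(s)
        np.testing.assert_allclose(out.intensity, 5.0)

    def test_window3_order2_identity(self):
        w = np.arange(800.0, 901.0)
        rng = np.random.default_rng(0)
        s = rm.RamanSpectrum(w, rng.normal(size=w.size))
        out = rm.smooth(s, window=3, order=2)
        np.testing.assert_allclose(out.intensity, s.intensity, atol=1e-10)

    def test_noise_variance_reduction(self, rng):
        # oracle: sd ratio equals sqrt(sum of squared SG weights)
        w = np.arange(800.0, 2001.0)
        noise = rng.normal(0.0, 1.0, size=w.size)
        out = rm.smooth(rm.RamanSpectrum(w, noise), window=11, order=3)
        factor = float(np.sqrt(np.sum(savgol_coeffs(11, 3) ** 2)))
        sd = out.intensity[20:-20].std()
        assert sd < 0.6
        assert sd == pytest.approx(factor, rel=0.15)

    def test_peak_position_preserved(self):
        w = np.arange(800.0, 2001.0)
        y = rm.pseudo_voigt(w, 1000.0, 1247.0, 40.0, 0.5)
        out = rm.smooth(rm.RamanSpectrum(w, y), window=11, order=3)
        assert abs(w[np.argmax(out.intensity)] - 1247.0) <= 1.0

    def test_window_larger_than_spectrum(self):
        s = rm.RamanSpectrum(np.arange(800.0, 805.0), np.zeros(5))
        with pytest.raises(ValueError):
            rm.smooth(s, window=11)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            rm.smooth(flat_spectrum(), window=10)


class TestBaseline:
    def test_pure_polynomial_removed_exactly(self):
        w = np.arange(800.0, 2001.0)
        y = 5.0 + 0.01 * (w - 1400.0) + 2e-5 * (w - 1400.0) ** 2
        out = rm.subtract_baseline(rm.RamanSpectrum(w, y), degree=2)
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.max(np.abs(y))

    def test_peak_height_recovered_on_polynomial(self):
        w = np.arange(800.0, 2001.0)
        base = 100.0 + 0.05 * (w - 800.0)
        peak = rm.pseudo_voigt(w, 1000.0, 1247.0, 30.0, 0.4)
        out = rm.subtract_baseline(rm.RamanSpectrum(w, base + peak), degree=5)
        height = out.intensity[np.argmin(np.abs(w - 1247.0))]
        assert height == pytest.approx(1000.0, rel=0.02)

    def test_degree_zero_constant(self):
        out = rm.subtract_baseline(flat_spectrum(value=42.0), degree=0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            rm.subtract_baseline(flat_spectrum(), degree=-1)


class TestCrop:
    def test_window_endpoints_retained(self):
        w = np.arange(400.0, 2401.0)
        s = rm.RamanSpectrum(w, np.zeros(w.size))
        out = rm.crop(s, 800.0, 2000.0)
        assert out.wavenumber[0] == 800.0
        assert out.wavenumber[-1] == 2000.0

    def test_full_range_identity(self):
        s = flat_spectrum()
        out = rm.crop(s, 800.0, 2000.0)
        np.testing.assert_array_equal(out.wavenumber, s.wavenumber)

    def test_empty_window_errors(self):
        with pytest.raises(rm.EmptyWindowError):
            rm.crop(flat_spectrum(), 3000.0, 4000.0)

    def test_inverted_bounds(self):
        with pytest.raises(ValueError):
            rm.crop(flat_spectrum(), 2000.0, 800.0)


class TestFitPeaks:
    def test_single_peak_roundtrip(self):
        w = np.arange(800.0, 2001.0)
        y = rm.pseudo_voigt(w, 1000.0, 1247.0, 40.0, 0.5)
        (peak,) = rm.fit_peaks(rm.RamanSpectrum(w, y), [1247.0])
        assert peak.center == pytest.approx(1247.0, abs=1247 * 1e-3)
        assert peak.height == pytest.approx(1000.0, rel=1e-3)
        assert peak.fwhm == pytest.approx(40.0, rel=1e-3)
        assert peak.eta == pytest.approx(0.5, abs=1e-3)

    def test_two_overlapping_peaks(self):
        w = np.arange(800.0, 2001.0)
        y = rm.pseudo_voigt(w, 3000.0, 1247.0, 55.0, 0.4) + rm.pseudo_voigt(
            w, 1400.0, 1325.0, 60.0, 0.6
        )
        peaks = rm.fit_peaks(rm.RamanSpectrum(w, y), [1247.0, 1325.0])
        assert abs(peaks[0].center - 1247.0) < 1.0
        assert abs(peaks[1].center - 1325.0) < 1.0

    def test_flat_zero_spectrum_errors(self):
        with pytest.raises(rm.FitError):
            rm.fit_peaks(flat_spectrum(value=0.0), [1247.0])

    def test_center_outside_window_rejected(self):
        with pytest.raises(ValueError):
            rm.fit_peaks(flat_spectrum(value=1.0), [5000.0])

    def test_deterministic(self):
        w = np.arange(800.0, 2001.0)
        rng = np.random.default_rng(7)
        y = rm.pseudo_voigt(w, 900.0, 1250.0, 45.0, 0.7) + rng.normal(0, 5, w.size)
        s = rm.RamanSpectrum(w, y)
        a = rm.fit_peaks(s, [1247.0])
        b = rm.fit_peaks(s, [1247.0])
        assert a[0] == b[0]

    def test_scale_equivariance(self):
        w = np.arange(800.0, 2001.0)
        y = rm.pseudo_voigt(w, 2000.0, 1247.0, 40.0, 0.5) + rm.pseudo_voigt(
            w, 900.0, 1325.0, 55.0, 0.5
        )
        c = 3.7
        p1 = rm.fit_peaks(rm.RamanSpectrum(w, y), [1247.0, 1325.0])
        p2 = rm.fit_peaks(rm.RamanSpectrum(w, c * y), [1247.0, 1325.0])
        assert p2[0].height / p1[0].height == pytest.approx(c, rel=1e-3)
        r1 = rm.band_ratio(p1).ratio
        r2 = rm.band_ratio(p2).ratio
        assert r1 == pytest.approx(r2, rel=1e-3)


class TestBandRatio:
    def test_printed_15s_first_sample(self):
        peaks = [peak_result(3227.29, 1247.30), peak_result(1409.34, 1322.71)]
        assert round(rm.band_ratio(peaks).ratio, 2) == 2.29

    def test_printed_30s_first_sample(self):
        peaks = [peak_result(3484.08, 1266.29), peak_result(5100.98, 1303.85)]
        assert round(rm.band_ratio(peaks).ratio, 2) == 0.68

    def test_equal_heights(self):
        peaks = [peak_result(500.0, 1247.0), peak_result(500.0, 1325.0)]
        assert rm.band_ratio(peaks).ratio == 1.0

    def test_missing_band_errors(self):
        with pytest.raises(rm.BandAssignmentError):
            rm.band_ratio([peak_result(100.0, 1247.0)])

    def test_shifted_centers_assigned(self):
        # red/blue-shifted centres (1266, 1305) still land in the +-40 windows
        peaks = [peak_result(100.0, 1266.0), peak_result(50.0, 1305.0)]
        ratio = rm.band_ratio(peaks)
        assert ratio.numerator.center == 1266.0
        assert ratio.denominator.center == 1305.0


class TestGroupMeans:
    def test_printed_group_means(self):
        grouped = {
            g: [n / d for n, d in rows] for g, rows in PRINTED_INTENSITIES.items()
        }
        means = rm.group_mean_ratio(grouped)
        assert means[15.0] == pytest.approx(2.2927, abs=5e-5)
        assert means[25.0] == pytest.approx(1.8351, abs=5e-5)
        assert means[30.0] == pytest.approx(0.7983, abs=5e-5)

    def test_single_ratio_identity(self):
        assert rm.group_mean_ratio({20.0: [1.72]})[20.0] == 1.72

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rm.group_mean_ratio({20.0: []})


class TestParameterRecovery:
    def test_bias_at_snr_50(self, rng):
        # 200 replicates, SNR = height / noise sd = 50
        w = np.arange(1100.0, 1501.0)
        height, center, fwhm, eta = 3000.0, 1247.0, 40.0, 0.5
        sd = height / 50.0
        centers, heights = [], []
        clean = rm.pseudo_voigt(w, height, center, fwhm, eta) + rm.pseudo_voigt(
            w, 1400.0, 1325.0, 55.0, 0.5
        )
        for _ in range(200):
            y = clean + rng.normal(0.0, sd, size=w.size)
            peaks = rm.fit_peaks(rm.RamanSpectrum(w, y), [1247.0, 1325.0])
            centers.append(peaks[0].center)
            heights.append(peaks[0].height)
        assert abs(np.mean(centers) - center) < 0.5
        assert abs(np.mean(heights) - height) / height < 0.02
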