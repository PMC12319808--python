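"""Multitaper estimation and aperiodic/periodic spectral parameterization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctspectra.spectral import (
    AperiodicComponent, FitSettings, PowerSpectrum, aperiodic_model,
    average_spectra, detrend_epoch, extract_peaks, fit_aperiodic,
    fit_spectral_model, gaussian_model, multitaper_psd, select_alpha,
    PeakComponent,
)


def power_law_spectrum(b=2.0, X=1.5, peaks=(), noise_sd=0.0, seed=0,
                       df=0.25, lo=4.0, hi=40.0):
    freqs = np.arange(lo, hi + df / 2, df)
    logp = b - X * np.log10(freqs)
    for a, c, w in peaks:
        logp = logp + gaussian_model(freqs, a, c, w)
    if noise_sd:
        logp = logp + noise_sd * np.random.default_rng(
            seed).standard_normal(freqs.size)
    return PowerSpectrum(freqs, 10.0 ** logp)


class TestDetrend:
    def test_pure_line_removed(self):
        t = np.arange(100, dtype=float)
        assert detrend_epoch(3.0 + 0.5 * t) == pytest.approx(
            np.zeros(100), abs=1e-9)

    def test_sinusoid_recovered_with_zero_residual_slope(self):
        t = np.arange(2000) / 200.0
        x = np.sin(2 * np.pi * 3 * t) + 2.0 + 0.3 * t
        out = detrend_epoch(x)
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 1e-10

    def test_too_short(self):
        with pytest.raises(ValueError):
            detrend_epoch([1.0])


class TestMultitaper:
    def test_time_bandwidth_product_recorded(self, rng):
        x = rng.standard_normal(60 * 250)
        spec = multitaper_psd(x, fs=250.0, half_bandwidth=0.6, n_tapers=45)
        assert spec.meta["time_bandwidth"] == pytest.approx(36.0)
        assert spec.meta["n_tapers"] == 45

    def test_taper_bound_enforced(self, rng):
        x = rng.standard_normal(5 * 250)
        # 5 s x 0.6 Hz: 2TW-1 = 5 tapers allowed
        multitaper_psd(x, 250.0, 0.6, n_tapers=5)
        with pytest.raises(ValueError, match="tapers"):
            multitaper_psd(x, 250.0, 0.6, n_tapers=6)

    def test_small_time_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError, match="time-bandwidth"):
            multitaper_psd(rng.standard_normal(250), 250.0, 0.5)

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(60 * 250)
        spec = multitaper_psd(x, 250.0, half_bandwidth=0.6, n_tapers=45,
                              detrend=False)
        total = np.trapezoid(spec.power, spec.freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_sinusoid_power_concentrated(self):
        fs, f0 = 200.0, 10.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        spec = multitaper_psd(x, fs, half_bandwidth=0.6, n_tapers=45)
        in_band = np.abs(spec.freqs - f0) <= 0.6
        frac = (np.trapezoid(spec.power[in_band], spec.freqs[in_band])
                / np.trapezoid(spec.power, spec.freqs))
        assert frac > 0.95
        assert np.trapezoid(spec.power, spec.freqs) == pytest.approx(
            np.var(x), rel=0.05)

    def test_white_noise_log_log_slope_near_zero(self, rng):
        x = rng.standard_normal(120 * 250)
        spec = multitaper_psd(x, 250.0, half_bandwidth=0.6, n_tapers=45)
        ap = fit_aperiodic(spec, FitSettings(freq_range=(4, 100)))
        assert abs(ap.exponent) < 0.05

    def test_agrees_with_mne_reference(self, rng):
        from mne.time_frequency import psd_array_multitaper

        fs = 200.0
        t = np.arange(int(60 * fs)) / fs
        x = rng.standard_normal(t.size) + np.sin(2 * np.pi * 10 * t)
        mine = multitaper_psd(x, fs, half_bandwidth=0.6, n_tapers=45,
                              detrend=False)
        # mne's bandwidth argument is the full width 2W
        ref, freqs = psd_array_multitaper(
            x, fs, bandwidth=1.2, adaptive=False, normalization="full",
            verbose="error")
        m = (freqs > 1) & (freqs < 90)
        ratio = np.interp(freqs[m], mine.freqs, mine.power) / ref[m]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.02)


class TestFitAperiodic:
    def test_exact_power_law(self):
        ap = fit_aperiodic(power_law_spectrum(b=2.0, X=1.5), FitSettings())
        assert ap.offset == pytest.approx(2.0, abs=1e-6)
        assert ap.exponent == pytest.approx(1.5, abs=1e-6)
        assert ap.knee is None

    def test_flat_spectrum(self):
        ap = fit_aperiodic(power_law_spectrum(b=1.0, X=0.0), FitSettings())
        assert ap.exponent == pytest.approx(0.0, abs=1e-8)

    def test_robust_to_peak_beats_naive_fit(self):
        spec = power_law_spectrum(b=2.0, X=1.5, peaks=[(0.8, 10.0, 1.5)])
        ap = fit_aperiodic(spec, FitSettings())
        # naive oracle: single least-squares pass over all bins
        naive = np.polyfit(np.log10(spec.freqs), np.log10(spec.power), 1)
        err_robust = abs(ap.exponent - 1.5) + abs(ap.offset - 2.0)
        err_naive = abs(-naive[0] - 1.5) + abs(naive[1] - 2.0)
        assert err_robust < err_naive / 5

    def test_too_few_bins(self):
        spec = PowerSpectrum(np.array([5.0, 6.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="bins"):
            fit_aperiodic(spec, FitSettings())

    def test_knee_mode_reduces_to_fixed_for_zero_knee(self):
        spec = power_law_spectrum(b=2.0, X=1.5)
        ap = fit_aperiodic(spec, FitSettings(aperiodic_mode="knee"))
        assert ap.exponent == pytest.approx(1.5, abs=0.05)
        assert ap.knee == pytest.approx(0.0, abs=1.0)


class TestExtractPeaks:
    def test_single_gaussian_recovered(self):
        freqs = np.arange(4, 40.01, 0.25)
        rng = np.random.default_rng(7)
        flat = gaussian_model(freqs, 0.6, 10.0, 1.2) \
            + 0.01 * rng.standard_normal(freqs.size)
        peaks = extract_peaks(freqs, flat, FitSettings())
        assert len(peaks) >= 1
        assert abs(peaks[0].center - 10.0) < 0.1
        assert peaks[0].power == pytest.approx(0.6, abs=0.05)

    def test_two_separated_gaussians_in_height_order(self):
        freqs = np.arange(4, 40.01, 0.25)
        flat = (gaussian_model(freqs, 0.7, 10.0, 1.0)
                + gaussian_model(freqs, 0.4, 22.0, 1.5))
        peaks = extract_peaks(freqs, flat, FitSettings())
        assert len(peaks) == 2
        assert peaks[0].power > peaks[1].power
        assert abs(peaks[0].center - 10.0) < 0.1
        assert abs(peaks[1].center - 22.0) < 0.1

    def test_max_peaks_respected(self):
        freqs = np.arange(4, 40.01, 0.25)
        flat = sum(gaussian_model(freqs, 0.5, c, 0.8)
                   for c in (6, 10, 14, 18, 22, 26, 30))
        peaks = extract_peaks(freqs, np.asarray(flat),
                              FitSettings(max_peaks=3))
        assert len(peaks) <= 3

    def test_stricter_threshold_means_fewer_detections(self):
        freqs = np.arange(4, 40.01, 0.25)
        rng = np.random.default_rng(3)
        flat = 0.05 * rng.standard_normal(freqs.size)
        loose = extract_peaks(freqs, flat, FitSettings(peak_threshold=1.0))
        strict = extract_peaks(freqs, flat, FitSettings(peak_threshold=4.0))
        assert len(strict) <= len(loose)

    def test_pure_noise_rarely_yields_tall_peaks(self):
        """Spurious detections on structureless residuals stay near the
        noise floor: across seeds, no fitted peak rises above 4 noise
        standard deviations, and a 4-sd threshold yields no detections at
        all in the large majority of draws."""
        freqs = np.arange(4, 40.01, 0.5)
        n_any_strict = 0
        for seed in range(40):
            flat = 0.05 * np.random.default_rng(seed).standard_normal(
                freqs.size)
            peaks = extract_peaks(freqs, flat, FitSettings())
            assert all(p.power < 5 * 0.05 for p in peaks)
            strict = extract_peaks(freqs, flat,
                                   FitSettings(peak_threshold=4.0))
            n_any_strict += bool(strict)
        assert n_any_strict <= 4


class TestFitSpectralModel:
    def test_noiseless_recovery_all_five_parameters(self):
        spec = power_law_spectrum(b=2.0, X=1.5, peaks=[(0.6, 10.0, 1.2)],
                                  df=1 / 6)
        fit = fit_spectral_model(spec, FitSettings())
        alpha = select_alpha(fit)
        assert fit.aperiodic.offset == pytest.approx(2.0, abs=1e-2)
        assert fit.aperiodic.exponent == pytest.approx(1.5, abs=1e-2)
        assert alpha.power == pytest.approx(0.6, abs=1e-2)
        assert alpha.center == pytest.approx(10.0, abs=1e-2)
        assert alpha.width == pytest.approx(1.2, abs=1e-2)

    def test_zero_peak_spectrum_gives_empty_list(self):
        fit = fit_spectral_model(power_law_spectrum(b=1.0, X=1.0),
                                 FitSettings())
        assert fit.peaks == []
        assert fit.model() == pytest.approx(
            aperiodic_model(fit.freqs, fit.aperiodic))

    def test_reconstruction_error_identity(self):
        spec = power_law_spectrum(b=2.0, X=1.2, peaks=[(0.5, 11.0, 1.0)],
                                  noise_sd=0.03, seed=5)
        fit = fit_spectral_model(spec, FitSettings())
        resid = fit.log_power - fit.model()
        assert fit.error == pytest.approx(float(np.mean(np.abs(resid))))
        ss_res = float(np.sum(resid ** 2))
        ss_tot = float(np.sum((fit.log_power - fit.log_power.mean()) ** 2))
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot)

    @given(logk=st.floats(-2, 2))
    def test_scale_equivariance(self, logk):
        spec = power_law_spectrum(b=2.0, X=1.5, peaks=[(0.6, 10.0, 1.2)],
                                  noise_sd=0.02, seed=9)
        scaled = PowerSpectrum(spec.freqs, spec.power * 10.0 ** logk)
        f0 = fit_spectral_model(spec, FitSettings())
        f1 = fit_spectral_model(scaled, FitSettings())
        assert f1.aperiodic.offset - f0.aperiodic.offset == pytest.approx(
            logk, abs=1e-3)
        assert f1.aperiodic.exponent == pytest.approx(
            f0.aperiodic.exponent, abs=1e-3)
        a0, a1 = select_alpha(f0), select_alpha(f1)
        assert a1.center == pytest.approx(a0.center, abs=1e-3)
        assert a1.power == pytest.approx(a0.power, abs=1e-3)

    def test_exponent_recovery_across_range(self):
        """Monte-Carlo exponent recovery: error < 0.05 clean, < 0.15 with
        an alpha peak and realistic estimator noise."""
        for X in (0.5, 1.5, 3.0):
            fit = fit_spectral_model(power_law_spectrum(b=1.5, X=X),
                                     FitSettings())
            assert abs(fit.aperiodic.exponent - X) < 0.05
        errs = []
        for seed in range(10):
            spec = power_law_spectrum(b=1.5, X=1.5,
                                      peaks=[(0.6, 10.0, 1.2)],
                                      noise_sd=0.05, seed=seed)
            fit = fit_spectral_model(spec, FitSettings())
            errs.append(abs(fit.aperiodic.exponent - 1.5))
        assert np.mean(errs) < 0.15


class TestSelectAlpha:
    def _fit_with(self, peaks):
        spec = power_law_spectrum()
        fit = fit_spectral_model(spec, FitSettings())
        fit.peaks = peaks
        return fit

    def test_max_power_rule(self):
        fit = self._fit_with([PeakComponent(0.5, 10.0, 1.0),
                              PeakComponent(0.7, 9.0, 1.0)])
        assert select_alpha(fit).center == 9.0

    def test_band_exclusion(self):
        fit = self._fit_with([PeakComponent(0.5, 5.0, 1.0),
                              PeakComponent(0.7, 20.0, 1.0)])
        assert select_alpha(fit) is None

    def test_single_alpha_identity(self):
        pk = PeakComponent(0.4, 11.0, 1.0)
        assert select_alpha(self._fit_with([pk])) is pk


class TestAverageSpectra:
    def test_average_and_grid_check(self):
        s1 = power_law_spectrum(b=1.0, X=1.0)
        s2 = power_law_spectrum(b=2.0, X=1.0)
        avg = average_spectra([s1, s2])
        assert avg.power == pytest.approx((s1.power + s2.power) / 2)
        bad = PowerSpectrum(s1.freqs + 0.1, s1.power)
        with pytest.raises(ValueError, match="grids"):
            average_spectra([s1, bad])
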