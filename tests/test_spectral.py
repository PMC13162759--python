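"""Welch spectra, aperiodic/peak decomposition, IAF, condition contrasts."""

import numpy as np
import pytest
from scipy import stats

from narousal import (aperiodic_contrast, estimate_iaf, fit_spectral_model,
                      frequency_cluster_test, welch_psd)
from narousal.spectral import NoAlphaPeakError
from narousal.experiments import synthetic_spectrum
from narousal.synthetic import narrowband_noise, pink_noise


class TestWelch:
    def test_tone_localized_at_its_frequency(self):
        fs = 200.0
        t = np.arange(int(20 * fs)) / fs
        spec = welch_psd(np.sin(2 * np.pi * 10.0 * t), fs)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(10.0,
                                                                  abs=0.5)

    def test_zero_padding_gives_tenth_hz_grid(self, rng):
        spec = welch_psd(rng.standard_normal(int(120 * 200)), 200.0,
                         window_s=2.0, zero_pad_s=10.0)
        assert spec.resolution == pytest.approx(0.1)

    def test_white_noise_fits_flat(self, rng):
        spec = welch_psd(rng.standard_normal(int(120 * 200)), 200.0)
        fit = fit_spectral_model(spec)
        assert abs(fit.aperiodic.exponent) < 0.1

    def test_window_longer_than_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            welch_psd(rng.standard_normal(100), 200.0, window_s=1.28)


class TestSpectralFit:
    def test_pure_line_recovered_without_peaks(self):
        freqs = np.arange(1.0, 40.05, 0.25)
        spec = synthetic_spectrum(freqs, offset=1.0, exponent=1.2)
        fit = fit_spectral_model(spec)
        assert fit.aperiodic.exponent == pytest.approx(1.2, abs=0.05)
        assert fit.aperiodic.offset == pytest.approx(1.0, abs=0.05)
        assert fit.peaks == []

    def test_single_peak_center_recovered(self):
        freqs = np.arange(1.0, 40.05, 0.25)
        spec = synthetic_spectrum(freqs, 1.0, 1.0,
                                  peaks=[(10.0, 0.5, 1.5)])
        fit = fit_spectral_model(spec)
        assert len(fit.peaks) == 1
        assert fit.peaks[0].center == pytest.approx(10.0, abs=0.2)
        assert fit.peaks[0].height == pytest.approx(0.5, abs=0.1)

    def test_subthreshold_peak_not_reported(self):
        freqs = np.arange(1.0, 40.05, 0.25)
        spec = synthetic_spectrum(freqs, 1.0, 1.0,
                                  peaks=[(10.0, 0.10, 1.5)])
        fit = fit_spectral_model(spec)
        assert fit.peaks == []

    def test_reconstruction_within_fit_error(self, rng):
        x = pink_noise(int(120 * 200), 200.0, 1.5, rng)
        x += 1.2 * narrowband_noise(int(120 * 200), 200.0, 10.0, 0.8, rng)
        spec = welch_psd(x, 200.0)
        fit = fit_spectral_model(spec)
        resid = np.abs(spec.crop(2, 40).power - fit.model())
        # aperiodic + peaks + residual reproduces the input: the quoted
        # fit_error IS the mean absolute residual of the full model
        assert resid.mean() == pytest.approx(fit.fit_error, abs=1e-12)
        assert fit.fit_error < 0.2

    def test_exponent_recovered_from_pink_noise(self, rng):
        x = pink_noise(int(120 * 200), 200.0, 1.5, rng)
        fit = fit_spectral_model(welch_psd(x, 200.0))
        assert fit.aperiodic.exponent == pytest.approx(1.5, abs=0.1)

    def test_too_few_bins_rejected(self):
        freqs = np.array([2.0, 5.0, 10.0])
        spec = synthetic_spectrum(freqs, 1.0, 1.0)
        with pytest.raises(ValueError):
            fit_spectral_model(spec)


class TestIaf:
    def test_constructed_alpha_peak_found_on_grid(self):
        freqs = np.arange(1.0, 40.05, 0.1)
        spec = synthetic_spectrum(freqs, 1.0, 1.2, peaks=[(9.7, 0.6, 1.2)])
        est = estimate_iaf(spec)
        assert est.iaf == pytest.approx(9.7, abs=0.1)
        assert est.low_band == pytest.approx((est.iaf - 1.0, est.iaf))

    def test_highest_alpha_peak_wins(self):
        freqs = np.arange(1.0, 40.05, 0.1)
        spec = synthetic_spectrum(freqs, 1.0, 1.0,
                                  peaks=[(9.0, 0.6, 1.0), (12.0, 0.3, 1.0)])
        assert estimate_iaf(spec).iaf == pytest.approx(9.0, abs=0.1)

    def test_no_peak_raises_fallback_error(self):
        freqs = np.arange(1.0, 40.05, 0.1)
        spec = synthetic_spectrum(freqs, 1.0, 1.0)
        with pytest.raises(NoAlphaPeakError):
            estimate_iaf(spec)


class TestAperiodicContrast:
    def test_identical_conditions(self, rng):
        x = rng.standard_normal(10) + 1.5
        res = aperiodic_contrast(x, x.copy())
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_shift_is_degenerate(self, rng):
        x = rng.standard_normal(10)
        with pytest.raises(ValueError, match="degenerate"):
            aperiodic_contrast(x, x + 0.3)

    def test_matches_closed_form(self, rng):
        a = 1.5 + 0.25 * rng.standard_normal(25)
        b = a + 0.1 + 0.25 * rng.standard_normal(25)
        res = aperiodic_contrast(a, b)
        d = b - a
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(25))
        assert res.t == pytest.approx(expected, abs=1e-12)
        assert res.df == 24


class TestFrequencyClusterTest:
    freqs = np.arange(2.0, 18.01, 0.25)

    def test_identical_conditions_give_no_clusters(self, rng):
        rest = rng.standard_normal((10, self.freqs.size))
        clusters = frequency_cluster_test(rest, rest + 1e-12 *
                                          rng.standard_normal(rest.shape),
                                          self.freqs, n_perm=200, seed=1)
        assert all(c.p_corrected > 0.5 for c in clusters)

    def test_injected_alpha_suppression_detected(self):
        # d ~ 1 suppression over 9-14 Hz must surface as a negative
        # cluster covering the injected bins in nearly every replicate
        band = (self.freqs >= 9) & (self.freqs <= 14)
        hits = 0
        n_reps = 40
        for rep in range(n_reps):
            g = np.random.default_rng(1000 + rep)
            rest = g.standard_normal((25, self.freqs.size))
            movie = g.standard_normal((25, self.freqs.size))
            movie[:, band] -= 1.0
            clusters = frequency_cluster_test(rest, movie, self.freqs,
                                              n_perm=500, seed=rep)
            sig = [c for c in clusters
                   if c.p_corrected < 0.05 and c.sign < 0]
            if any(np.isin(c.members,
                           np.flatnonzero(band)).mean() > 0.5
                   for c in sig):
                hits += 1
        assert hits / n_reps >= 0.9

    def test_low_n_perm_warns(self, rng):
        rest = rng.standard_normal((6, self.freqs.size))
        with pytest.warns(RuntimeWarning, match="n_perm"):
            frequency_cluster_test(rest, rest + rng.standard_normal(
                rest.shape), self.freqs, n_perm=50, seed=0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            frequency_cluster_test(rng.standard_normal((5, 10)),
                                   rng.standard_normal((5, 11)),
                                   np.arange(10.0))

    def test_reduces_to_per_bin_ttest_prob(self, rng):
        # single supra-threshold bin forms a one-bin cluster whose mass
        # equals |t| of that bin
        rest = rng.standard_normal((12, self.freqs.size))
        movie = rest.copy() + 0.02 * rng.standard_normal(rest.shape)
        movie[:, 30] += 2.0
        clusters = frequency_cluster_test(rest, movie, self.freqs,
                                          n_perm=200, seed=5)
        sig = [c for c in clusters if 30 in c.members]
        assert len(sig) == 1
        d = movie[:, 30] - rest[:, 30]
        t30 = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert sig[0].mass >= abs(t30) - 1e-9
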