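"""Spectral layer: epoching, artifact flags, Welch PSD, broadband power
and the aperiodic fit, each checked against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as scipy_signal

from periglioma.cohort import add_oscillation, synthesize_aperiodic_series
from periglioma.spectral import (AperiodicFit,
                                 InsufficientCleanEpochsError, PowerSpectrum,
                                 RegionalTimeSeries, broadband_power,
                                 compute_psd_welch, fir_bandpass, fit_aperiodic,
                                 flag_artifact_epochs, power_at_frequency,
                                 segment_epochs, select_epochs_first_clean,
                                 select_epochs_max_alpha, summarize_activity,
                                 _welch)


def _series(data, fs=1250.0):
    return RegionalTimeSeries("s1", np.atleast_2d(data), fs)


class TestSegmentEpochs:
    def test_five_minute_recording_yields_22_epochs(self):
        ts = _series(np.zeros((2, int(300 * 1250))))
        eps = segment_epochs(ts)
        assert eps.n_epochs == 22
        assert eps.n_samples == 16375

    def test_exactly_one_epoch(self):
        ts = _series(np.zeros(int(round(13.1 * 1250))))
        assert segment_epochs(ts).n_epochs == 1

    def test_shorter_than_one_epoch_errors(self):
        ts = _series(np.zeros(int(13.0 * 1250)))
        with pytest.raises(ValueError, match="shorter than one"):
            segment_epochs(ts)

    def test_trailing_partial_epoch_discarded(self):
        fs = 100.0
        ts = _series(np.arange(int(13.1 * fs * 2.5)), fs=fs)
        eps = segment_epochs(ts)
        assert eps.n_epochs == 2
        # epochs are consecutive, non-overlapping, from the start
        assert eps.data[0, 0, 0] == 0
        assert eps.data[1, 0, 0] == eps.n_samples


class TestArtifactFlags:
    def test_false_positive_rate_on_clean_epochs(self, rng):
        data = rng.standard_normal((200, 2, 400))
        eps = segment_epochs(_series(rng.standard_normal((2, 200 * 400)),
                                     fs=400 / 13.1))
        eps.data[:] = data
        flags = flag_artifact_epochs(eps, amplitude_z_threshold=8.0)
        assert flags.mean() <= 0.05

    def test_injected_transient_is_flagged(self, rng):
        fs = 400 / 13.1
        x = rng.standard_normal((2, 10 * 400))
        eps = segment_epochs(_series(x, fs=fs))
        scale = 1.4826 * np.median(np.abs(x[1] - np.median(x[1])))
        eps.data[4, 1, 100] += 10.0 * scale
        flags = flag_artifact_epochs(eps)
        assert flags[4]
        assert flags.sum() == 1

    def test_all_zero_epochs_not_flagged(self):
        eps = segment_epochs(_series(np.zeros((3, 2000)), fs=100 / 13.1))
        assert not flag_artifact_epochs(eps).any()


class TestEpochSelection:
    def _epochs(self, n=15, fs=100.0):
        data = np.arange(n * 1310 * 1.0).reshape(1, -1)
        return segment_epochs(_series(data, fs=fs))

    def test_first_clean_skips_flagged(self):
        eps = self._epochs()
        flags = np.zeros(eps.n_epochs, dtype=bool)
        flags[2] = True
        sel = select_epochs_first_clean(eps, flags, n=10)
        assert list(sel.epoch_indices) == [0, 1, 3, 4, 5, 6, 7, 8, 9, 10]

    def test_first_clean_error_reports_available(self):
        eps = self._epochs(n=9)
        with pytest.raises(InsufficientCleanEpochsError) as err:
            select_epochs_first_clean(eps, np.zeros(9, bool), n=10)
        assert err.value.available == 9

    def test_max_alpha_prefers_strong_10hz_epoch(self, rng):
        fs = 250.0
        n_ep, n_per = 12, int(round(13.1 * fs))
        x = rng.standard_normal((1, n_ep * n_per))
        t = np.arange(n_per) / fs
        x[0, 7 * n_per:8 * n_per] += 20 * np.sin(2 * np.pi * 10 * t)
        sel = select_epochs_max_alpha(segment_epochs(_series(x, fs=fs)), n=3)
        assert 7 in sel.epoch_indices

    def test_max_alpha_ties_break_to_earlier(self):
        fs = 100.0
        one = np.sin(2 * np.pi * 10 * np.arange(1310) / fs)
        eps = segment_epochs(_series(np.tile(one, 12), fs=fs))
        sel = select_epochs_max_alpha(eps, n=5)
        assert list(sel.epoch_indices) == [0, 1, 2, 3, 4]

    def test_max_alpha_identity_when_n_equals_total(self, rng):
        eps = segment_epochs(_series(rng.standard_normal((1, 4 * 1310)),
                                     fs=100.0))
        sel = select_epochs_max_alpha(eps, n=4)
        assert list(sel.epoch_indices) == [0, 1, 2, 3]


class TestWelchPsd:
    def test_matches_scipy_welch(self, rng):
        x = rng.standard_normal((2, 3, 5000))
        f1, p1 = scipy_signal.welch(x, fs=500.0, window="hamming",
                                    nperseg=1024, noverlap=512, axis=-1)
        f2, p2 = _welch(x, 500.0, 1024, 512)
        assert np.allclose(f1, f2)
        assert np.allclose(p1, p2, rtol=1e-10)

    def test_white_noise_parseval(self, rng):
        fs = 1250.0
        x = rng.standard_normal((1, int(60 * fs)))
        eps = segment_epochs(_series(x, fs=fs))
        spec = compute_psd_welch(eps, band=None)
        total = np.trapezoid(spec.power[0], spec.frequencies)
        assert abs(total - x.var()) / x.var() < 0.05

    def test_sinusoid_band_power_is_half_amplitude_squared(self):
        fs, amp = 1250.0, 3.0
        t = np.arange(int(30 * fs)) / fs
        x = amp * np.sin(2 * np.pi * 10.3 * t)
        eps = segment_epochs(_series(x, fs=fs))
        spec = compute_psd_welch(eps)
        power = broadband_power(spec)[0]
        assert abs(power - amp ** 2 / 2) / (amp ** 2 / 2) < 0.05

    def test_zero_signal_zero_psd(self):
        eps = segment_epochs(_series(np.zeros(int(13.1 * 1250))))
        assert np.all(compute_psd_welch(eps).power == 0)

    def test_nyquist_violation_rejected(self):
        eps = segment_epochs(_series(np.zeros(2000), fs=90.0))
        with pytest.raises(ValueError, match="Nyquist"):
            compute_psd_welch(eps)


class TestBroadbandPower:
    def test_constant_density_integrates_to_band_width(self):
        f = np.linspace(0.25, 48.5, 200)
        spec = PowerSpectrum(f, np.ones((1, 200)))
        assert broadband_power(spec)[0] == pytest.approx(47.5)

    def test_linearity(self, rng):
        f = np.linspace(0.4, 48.2, 150)
        p = rng.uniform(0.5, 2.0, (1, 150))
        one = broadband_power(PowerSpectrum(f, p))[0]
        two = broadband_power(PowerSpectrum(f, 2 * p))[0]
        assert two == pytest.approx(2 * one)

    def test_grid_not_covering_band_errors(self):
        f = np.linspace(1.0, 48.5, 100)
        with pytest.raises(ValueError, match="cover"):
            broadband_power(PowerSpectrum(f, np.ones((1, 100))))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 149), st.floats(0.01, 5.0))
    def test_adding_power_never_decreases_auc(self, idx, extra):
        f = np.linspace(0.4, 48.2, 150)
        base = np.ones((1, 150))
        bumped = base.copy()
        bumped[0, idx] += extra
        assert broadband_power(PowerSpectrum(f, bumped))[0] >= \
            broadband_power(PowerSpectrum(f, base))[0]


class TestAperiodicFit:
    def _spectrum(self, b, chi, k=0.0, bump=None, df=0.25):
        f = np.arange(0.5, 48.0 + df / 2, df)
        y = b - np.log10(k + f ** chi)
        if bump is not None:
            c, w, h = bump
            y = y + h * np.exp(-((f - c) ** 2) / (2 * w ** 2))
        return PowerSpectrum(f, 10.0 ** y[None, :])

    def test_noiseless_recovery_exact(self):
        fit = fit_aperiodic(self._spectrum(1.5, 1.2))[0]
        assert abs(fit.offset - 1.5) < 1e-6
        assert abs(fit.slope - 1.2) < 1e-6

    def test_alpha_bump_removed_before_fit(self):
        fit = fit_aperiodic(self._spectrum(1.5, 1.2,
                                           bump=(10.0, 1.5, 0.5)))[0]
        assert abs(fit.offset - 1.5) < 0.05
        assert abs(fit.slope - 1.2) < 0.05
        assert fit.n_peaks_removed > 0

    def test_flat_spectrum_gives_zero_slope_and_mean_offset(self):
        f = np.linspace(0.5, 48, 100)
        spec = PowerSpectrum(f, np.full((1, 100), 10.0 ** 0.7))
        fit = fit_aperiodic(spec)[0]
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.offset == pytest.approx(0.7)

    def test_idempotence_on_own_prediction(self):
        fit = fit_aperiodic(self._spectrum(1.1, 0.9,
                                           bump=(11.0, 1.0, 0.4)))[0]
        f = np.arange(0.5, 48.01, 0.25)
        refit = fit_aperiodic(PowerSpectrum(f, 10 ** fit.predict(f)[None]))[0]
        assert abs(refit.offset - fit.offset) < 1e-9
        assert abs(refit.slope - fit.slope) < 1e-9

    def test_free_knee_recovers_bend(self):
        fit = fit_aperiodic(self._spectrum(1.0, 2.0, k=5.0),
                            knee_mode="free")[0]
        assert abs(fit.offset - 1.0) < 0.05
        assert abs(fit.slope - 2.0) < 0.05
        assert abs(fit.knee - 5.0) < 0.5

    def test_fixed_knee_pins_zero(self):
        fit = fit_aperiodic(self._spectrum(1.0, 1.0))[0]
        assert fit.knee == 0.0

    def test_nonpositive_power_rejected(self):
        f = np.linspace(0.5, 48, 50)
        p = np.ones((1, 50))
        p[0, 10] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_aperiodic(PowerSpectrum(f, p))

    def test_too_few_points_rejected(self):
        f = np.linspace(0.5, 48, 5)
        with pytest.raises(ValueError, match="10 frequency points"):
            fit_aperiodic(PowerSpectrum(f, np.ones((1, 5))))


class TestScaleCovariance:
    def test_rescaling_shifts_offset_and_preserves_slope(self, rng):
        fs, c = 500.0, 3.7
        x = synthesize_aperiodic_series(1.0, 1.1, 0.0, fs,
                                        int(round(13.1 * fs)) * 6, rng)
        fits = []
        for series in (x, c * x):
            eps = segment_epochs(_series(series, fs=fs))
            fits.append(fit_aperiodic(compute_psd_welch(eps))[0])
        assert fits[1].offset - fits[0].offset == \
            pytest.approx(2 * np.log10(c), abs=1e-9)
        assert fits[1].slope == pytest.approx(fits[0].slope, abs=1e-9)


class TestSummaries:
    def _fits(self, offsets, slopes):
        return [AperiodicFit(b, s, 0.0, 0.01, 0) for b, s in
                zip(offsets, slopes)]

    def test_single_region_equals_itself(self):
        fits = self._fits([1.0, 2.0], [0.5, 1.5])
        s = summarize_activity(fits, [10.0, 20.0], [1], "global", "p1")
        assert (s.broadband_power, s.offset, s.slope) == (20.0, 2.0, 1.5)

    def test_identical_regions_mean_is_common_value(self):
        fits = self._fits([1.0] * 4, [0.8] * 4)
        s = summarize_activity(fits, [5.0] * 4, range(4), "global", "p1")
        assert (s.broadband_power, s.offset, s.slope) == (5.0, 1.0, 0.8)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            summarize_activity(self._fits([1.0], [1.0]), [1.0], [], "g")

    def test_power_at_lowest_frequency_diagnostic(self):
        f = np.linspace(0.25, 48.5, 3000)
        spec = PowerSpectrum(f, (1.0 / f)[None, :])
        assert power_at_frequency(spec, 0.5)[0] == pytest.approx(2.0,
                                                                 rel=1e-2)


class TestFirBandpass:
    def test_out_of_band_components_attenuated(self, rng):
        fs = 500.0
        t = np.arange(int(30 * fs)) / fs
        keep = np.sin(2 * np.pi * 10 * t)
        drop_lo = np.sin(2 * np.pi * 0.05 * t)
        drop_hi = np.sin(2 * np.pi * 120 * t)
        ts = _series(keep + drop_lo + drop_hi, fs=fs)
        filt = fir_bandpass(ts, zero_phase=True)
        spec = compute_psd_welch(segment_epochs(filt), band=None)
        f, p = spec.frequencies, spec.power[0]

        def band_peak(lo, hi):
            return p[(f >= lo) & (f <= hi)].max()

        assert band_peak(9, 11) > 100 * band_peak(100, 140)
        assert band_peak(9, 11) > 100 * band_peak(0.0, 0.2)

    def test_single_pass_is_causal_default(self, rng):
        fs = 250.0
        x = np.zeros((1, 2000))
        x[0, 1000] = 1.0  # impulse
        filt = fir_bandpass(_series(x, fs=fs))
        assert np.allclose(filt.data[0, :1000], 0.0)

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fir_bandpass(_series(np.zeros(1000), fs=90.0))


class TestOscillation:
    def test_zero_height_is_identity(self, rng):
        x = rng.standard_normal(4000)
        out = add_oscillation(x, 10.0, 1.5, 0.0, rng, 250.0)
        assert np.array_equal(out, x)

    def test_center_outside_passband_rejected(self, rng):
        with pytest.raises(ValueError, match="passband"):
            add_oscillation(np.zeros(100), 60.0, 1.0, 1.0, rng, 250.0)

    def test_bump_raises_band_power_at_center(self, rng):
        fs = 250.0
        n = int(round(13.1 * fs)) * 8
        x = synthesize_aperiodic_series(0.0, 0.0, 0.0, fs, n, rng)
        y = add_oscillation(x, 10.0, 1.0, 5.0, rng, fs)
        spec = compute_psd_welch(segment_epochs(_series(y, fs=fs)))
        in_bump = (spec.frequencies > 8) & (spec.frequencies < 12)
        away = (spec.frequencies > 20) & (spec.frequencies < 40)
        assert spec.power[0, in_bump].mean() > \
            3 * spec.power[0, away].mean()
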