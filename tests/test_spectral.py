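"""Spectral estimators: re-referencing, windowed spectra, band ratios, peaks."""

import numpy as np
import pytest

from deltatrack import synthetic
from deltatrack.spectral import (
    HUMAN_EEG_CONFIG,
    MOUSE_LFP_CONFIG,
    ChannelNotFoundError,
    InsufficientDataError,
    SpectralConfig,
    TimeSeriesRecording,
    absolute_delta_peak,
    exclude_noisy_channels,
    relative_delta_power,
    rereference_average,
    windowed_power_spectrum,
)

FS = 256


def _rec(arrays, fs=FS, labels=None, wake=None):
    arrays = np.atleast_2d(np.asarray(arrays, float))
    labels = labels or [f"c{i}" for i in range(arrays.shape[0])]
    return TimeSeriesRecording(arrays, fs, labels, wake)


def _tone(freq, duration=30.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestRereference:
    def test_common_mode_removed(self):
        s = _tone(3.0)
        rec = _rec(np.tile(s, (5, 1)), labels=list("abcde"))
        out = rereference_average(rec, list("abcde"))
        assert np.allclose(out.samples, 0.0)

    def test_mean_subtraction_arithmetic(self):
        s = _tone(3.0)
        rec = _rec(np.vstack([s, np.zeros((4, len(s)))]), labels=list("abcde"))
        out = rereference_average(rec, list("abcde"))
        assert np.allclose(out.samples[0], 0.8 * s)
        assert np.allclose(out.samples[1:], -0.2 * s)
        # output sums to zero at every sample
        assert np.allclose(out.samples.sum(axis=0), 0.0)

    def test_single_channel_goes_to_zero(self):
        rec = _rec(_tone(5.0), labels=["only"])
        out = rereference_average(rec, ["only"])
        assert np.allclose(out.samples, 0.0)

    def test_missing_channel_named(self):
        rec = _rec(_tone(3.0), labels=["O1"])
        with pytest.raises(ChannelNotFoundError, match="Pz"):
            rereference_average(rec, ["Pz"])

    def test_case_insensitive_labels(self):
        rec = _rec(_tone(3.0), labels=["Pz"])
        out = rereference_average(rec, ["PZ"])
        assert out.channel_labels == ["Pz"]


class TestWindowedSpectrum:
    def test_pure_tone_concentrates_on_its_bin(self):
        freqs, psd = windowed_power_spectrum(_rec(_tone(3.0, 60)), HUMAN_EEG_CONFIG)
        k3 = np.argmin(np.abs(freqs - 3.0))
        frac = psd[:, 0, k3] / psd[:, 0].sum(axis=1)
        assert (frac > 0.6).all()  # Hann main lobe: 2/3 of power on the bin
        away = np.abs(freqs - 3.0) > 2.0
        assert (psd[:, 0, away].max(axis=1) < 1e-6 * psd[:, 0, k3]).all()

    def test_partial_trailing_window_discarded(self):
        n = int(10.7 * FS)
        rec = _rec(np.random.default_rng(0).standard_normal(n))
        _, psd = windowed_power_spectrum(rec, HUMAN_EEG_CONFIG)
        assert psd.shape[0] == 10

    def test_too_short_recording_raises(self):
        rec = _rec(np.zeros(FS // 2))
        with pytest.raises(InsufficientDataError):
            windowed_power_spectrum(rec, HUMAN_EEG_CONFIG)

    def test_white_noise_spectrum_flat_at_analytic_level(self, rng):
        # E[PSD] for unit-variance white noise is 2/fs per one-sided bin
        sigma = 1.7
        rec = _rec(sigma * rng.standard_normal(1200 * FS))
        freqs, psd = windowed_power_spectrum(rec, HUMAN_EEG_CONFIG)
        mean_psd = psd[:, 0, :].mean(axis=0)
        # per-window demeaning dents the 1 Hz bin (DC removal bleeds through
        # the Hann main lobe); the flat-spectrum check starts at 2 Hz
        inner = (freqs >= 2) & (freqs < FS / 2)
        level = 2 * sigma**2 / FS
        assert np.abs(mean_psd[inner].mean() / level - 1) < 0.015
        assert np.abs(mean_psd[inner] / level - 1).max() < 0.12
        assert mean_psd[freqs == 1.0][0] < level  # the documented dent

    def test_parseval_on_random_signal(self, rng):
        x = rng.standard_normal(60 * FS)
        rec = _rec(x)
        freqs, psd = windowed_power_spectrum(rec, HUMAN_EEG_CONFIG)
        total = psd[:, 0, :].sum(axis=1) * (freqs[1] - freqs[0])
        frames = x[: 60 * FS].reshape(60, FS)
        var = frames.var(axis=1)
        # density scaling: summed power ~ window variance (taper-normalised)
        assert np.abs(total.mean() / var.mean() - 1) < 0.05

    def test_wake_mask_restricts_windows(self):
        rec = _rec(_tone(3.0, 30), wake=[(0.0, 10.0), (20.0, 25.0)])
        _, psd = windowed_power_spectrum(rec, HUMAN_EEG_CONFIG)
        assert psd.shape[0] == 15


class TestRelativeDelta:
    def test_pure_delta_tone_is_one(self):
        est = relative_delta_power(_rec(_tone(3.0, 30)))
        assert est.value == pytest.approx(1.0, abs=0.02)
        assert est.n_intervals == 30

    def test_equal_power_split_is_half(self):
        sig = _tone(3.0, 30) + _tone(10.0, 30, phase=1.0)
        est = relative_delta_power(_rec(sig))
        assert est.value == pytest.approx(0.5, abs=0.01)

    def test_white_noise_expectation_three_fiftieths(self, rng):
        # flat spectrum: 3 delta bins of 50 total -> 0.06, >=1e4 intervals
        rec = _rec(rng.standard_normal(10_000 * 128), fs=128)
        est = relative_delta_power(rec)
        assert est.n_intervals == 10_000
        assert est.value == pytest.approx(3 / 50, abs=3 * est.sem + 0.002)

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.standard_normal((3, 20 * FS))
        a = relative_delta_power(_rec(x)).value
        b = relative_delta_power(_rec(1000.0 * x)).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_power_intervals_dropped_and_counted(self):
        sig = np.concatenate([_tone(3.0, 10), np.zeros(5 * FS)])
        est = relative_delta_power(_rec(sig))
        assert est.n_dropped == 5
        assert est.n_intervals == 10

    def test_all_zero_recording_raises(self):
        with pytest.raises(InsufficientDataError):
            relative_delta_power(_rec(np.zeros(10 * FS)))

    def test_channel_combination_modes_agree_on_identical_channels(self, rng):
        x = rng.standard_normal(20 * FS)
        rec = _rec(np.tile(x, (3, 1)))
        cfg = SpectralConfig(channel_combine="mean_of_ratios")
        a = relative_delta_power(rec).value
        b = relative_delta_power(rec, cfg).value
        assert a == pytest.approx(b, rel=1e-10)

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.8])
    def test_programmed_power_recovery(self, target):
        rec = synthetic.make_synthetic_eeg(target, duration_s=120, seed=5)
        ref = rereference_average(rec, rec.channel_labels)
        est = relative_delta_power(ref)
        assert est.value == pytest.approx(target, abs=3 * est.sem)


MOUSE_FS = 3000.0


def _lfp(arrays, fs=MOUSE_FS):
    arrays = np.atleast_2d(np.asarray(arrays, float))
    labels = ["left", "right"][: arrays.shape[0]]
    return TimeSeriesRecording(arrays, fs, labels)


class TestAbsoluteDeltaPeak:
    def test_in_band_tone_peaks_at_its_bin(self):
        t = np.arange(0, 120, 1 / MOUSE_FS)
        sig = np.sin(2 * np.pi * 3 * t)
        est = absolute_delta_peak(_lfp([sig, sig]), last_minutes=None)
        freqs, psd = windowed_power_spectrum(_lfp([sig, sig]), MOUSE_LFP_CONFIG)
        spec = psd.mean(axis=(0, 1))
        inband = (freqs >= 1) & (freqs <= 5)
        peak_freq = freqs[inband][np.argmax(spec[inband])]
        assert abs(peak_freq - 3.0) <= 0.2  # 5 s window -> 0.2 Hz bins
        assert est.value == pytest.approx(spec[inband].max())

    def test_out_of_band_tone_ignored(self, rng):
        t = np.arange(0, 120, 1 / MOUSE_FS)
        noise = 0.2 * rng.standard_normal((2, len(t)))
        tone = np.sin(2 * np.pi * 8 * t)
        with_tone = absolute_delta_peak(_lfp(noise + tone), last_minutes=None)
        without = absolute_delta_peak(_lfp(noise), last_minutes=None)
        # the 8 Hz tone sits outside 1-5 Hz: the in-band peak stays at the
        # noise floor (up to residual taper sidelobe leakage)
        assert with_tone.value < 2 * without.value
        in_band_tone = absolute_delta_peak(
            _lfp(noise + np.sin(2 * np.pi * 3 * t)), last_minutes=None
        )
        assert in_band_tone.value > 20 * with_tone.value

    def test_hemisphere_averaging_is_linear(self):
        t = np.arange(0, 120, 1 / MOUSE_FS)
        a = np.sqrt(2.0) * np.sin(2 * np.pi * 3 * t)  # 2x power of b
        b = np.sin(2 * np.pi * 3 * t)
        est_ab = absolute_delta_peak(_lfp([a, b]), last_minutes=None)
        ea = absolute_delta_peak(_lfp([a]), last_minutes=None)
        eb = absolute_delta_peak(_lfp([b]), last_minutes=None)
        assert est_ab.value == pytest.approx((ea.value + eb.value) / 2, rel=1e-6)

    def test_monotone_in_tone_amplitude(self, rng):
        t = np.arange(0, 90, 1 / MOUSE_FS)
        noise = 0.05 * rng.standard_normal((2, len(t)))
        vals = []
        for amp in (0.5, 1.0, 2.0):
            sig = noise + amp * np.sin(2 * np.pi * 3 * t)
            vals.append(absolute_delta_peak(_lfp(sig), last_minutes=None).value)
        assert vals[0] < vals[1] < vals[2]

    def test_last_minutes_restriction(self):
        # a tone only in the final 10 min dominates when restricted
        t_early = np.arange(0, 300, 1 / MOUSE_FS)
        t_late = np.arange(0, 600, 1 / MOUSE_FS)
        sig = np.concatenate(
            [0.01 * np.sin(2 * np.pi * 3 * t_early),
             np.sin(2 * np.pi * 3 * t_late)]
        )
        full = absolute_delta_peak(_lfp([sig, sig]), last_minutes=None)
        last = absolute_delta_peak(_lfp([sig, sig]), last_minutes=10.0)
        assert last.value > full.value


class TestExcludeNoisy:
    def test_identical_clean_channels_kept(self, rng):
        x = rng.standard_normal(5 * FS)
        rec = _rec(np.tile(x, (2, 1)))
        out, report = exclude_noisy_channels(rec, 3.0)
        assert out.n_channels == 2
        assert report == []

    def test_loud_channel_excluded_by_robust_z(self, rng):
        chans = [rng.standard_normal(5 * FS) for _ in range(5)]
        chans.append(100.0 * rng.standard_normal(5 * FS))  # 1e4x power
        rec = _rec(np.array(chans))
        out, report = exclude_noisy_channels(rec, 3.0)
        assert out.n_channels == 5
        assert any("c5" in line and "robust z" in line for line in report)

    def test_rail_saturation_excluded(self, rng):
        clean = rng.standard_normal(5 * FS)
        pinned = clean.copy()
        pinned[FS : 2 * FS] = pinned.max()  # 1 s at rail
        rec = _rec(np.array([clean, clean * 1.01, pinned]))
        out, report = exclude_noisy_channels(rec, 5.0)
        assert "c2" not in out.channel_labels
        assert any("saturated" in line for line in report)
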