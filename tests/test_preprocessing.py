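"""Preprocessing chain: selection, normalisation, filtering, averaging, QC."""

import numpy as np
import pytest

from nirspulse.errors import (DegenerateChannelError, InsufficientDataError,
                              InvalidConfigError)
from nirspulse.preprocessing import (bandpass, epoch_average,
                                     normalize_channel, preprocess_channel,
                                     quality_control, select_channels)
from nirspulse.signals import ArterialPulsationSignal, RawChannel, RPeakEvents
from nirspulse.synthetic import ComponentWave, SimSpec, simulate_session

FS = 39.0625


def _channel(samples, fs=FS, cid="ch00", dist=30.0):
    return RawChannel(np.asarray(samples, float), fs, cid, dist)


class TestSelectChannels:
    def test_closed_interval_filter(self):
        chans = [_channel(np.ones(100), dist=d, cid=f"d{d}")
                 for d in (15, 20, 35, 60, 65)]
        kept = select_channels(chans, 20.0, 60.0)
        assert [c.sd_distance for c in kept] == [20, 35, 60]

    def test_all_in_range_is_identity(self):
        chans = [_channel(np.ones(100), dist=d) for d in (25, 30, 45)]
        assert select_channels(chans, 20.0, 60.0) == chans

    def test_empty_input_gives_empty_output(self):
        assert select_channels([], 20.0, 60.0) == []

    def test_inverted_window_rejected(self):
        with pytest.raises(InvalidConfigError):
            select_channels([], 60.0, 20.0)


class TestNormalize:
    def test_constant_trace_becomes_unity(self):
        out = normalize_channel(_channel(np.full(200, 7.0)))
        assert np.allclose(out.samples, 1.0)

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(0)
        out = normalize_channel(_channel(rng.uniform(50, 150, 500)))
        assert out.samples.mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_mean_trace_rejected(self):
        with pytest.raises(DegenerateChannelError):
            normalize_channel(_channel(np.zeros(100)))


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 1.2 * t)
        out = bandpass(_channel(x)).samples
        mid = slice(200, -200)  # avoid edge transients
        assert np.max(np.abs(out[mid])) == pytest.approx(1.0, rel=0.05)
        # zero phase: peak positions unchanged within one sample
        lag = np.argmax(np.correlate(out[mid], x[mid], "full")) - (
            len(x[mid]) - 1)
        assert abs(lag) <= 1

    def test_drift_attenuated(self):
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(_channel(x)).samples
        assert np.max(np.abs(out[200:-200])) < 0.10

    def test_dc_removed(self):
        t = np.arange(0, 60, 1 / FS)
        x = 5.0 + np.sin(2 * np.pi * 1.0 * t)
        out = bandpass(_channel(x)).samples
        assert abs(out.mean()) < 1e-3

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError):
            bandpass(_channel(np.ones(100)), 0.5, 30.0)


class TestEpochAverage:
    def _pulse_train(self, n_beats=20, period=1.024, noise_sd=0.0, seed=0):
        # period of exactly 40 samples at 39.0625 Hz: every epoch starts on
        # the sample grid, so repeated pulses are bit-identical
        fs = FS
        n = int(n_beats * period * fs) + 1
        t = np.arange(n) / fs
        pulse = np.zeros(n)
        beats = np.arange(0.0, n_beats * period, period)
        for r in beats:
            pulse += np.exp(-0.5 * ((t - r - 0.3072) / 0.05) ** 2)
        # events stop two beats early so every epoch sees identical content
        starts = beats[:-2]
        rng = np.random.default_rng(seed)
        x = -pulse + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
        return _channel(x, fs), RPeakEvents(starts), pulse, t

    def test_identical_epochs_average_to_negated_pulse(self):
        ch, events, pulse, t = self._pulse_train()
        s = epoch_average(ch, events)
        n = len(s.samples)
        expected = -ch.samples[:n]  # first epoch starts at t = 0
        assert np.allclose(s.samples, expected, atol=1e-12)

    def test_flip_makes_systole_positive(self):
        # raw trough during systole becomes a positive peak after the flip
        ch, events, _, _ = self._pulse_train()
        s = epoch_average(ch, events)
        assert s.samples.max() == pytest.approx(1.0, abs=2e-3)
        assert ch.samples.min() == pytest.approx(-1.0, abs=2e-3)

    def test_residual_noise_shrinks_as_sqrt_n(self):
        # Monte-Carlo: residual SD after averaging N epochs ~ sigma/sqrt(N)
        sigma, n_beats = 0.5, 52
        ch, events, _, _ = self._pulse_train(n_beats=n_beats, noise_sd=sigma,
                                             seed=7)
        s = epoch_average(ch, events)
        clean_ch, clean_events, _, _ = self._pulse_train(n_beats=n_beats)
        clean = epoch_average(clean_ch, clean_events)
        resid = s.samples - clean.samples
        expected = sigma / np.sqrt(s.n_epochs_averaged)
        assert resid.std() == pytest.approx(expected, rel=0.20)

    def test_too_few_epochs_rejected(self):
        ch, _, _, _ = self._pulse_train(n_beats=20)
        with pytest.raises(InsufficientDataError):
            epoch_average(ch, RPeakEvents(np.array([0.0, 1.0, 18.0])),
                          epoch_length=3.0)

    def test_epoch_metadata_recorded(self):
        ch, events, _, _ = self._pulse_train()
        s = epoch_average(ch, events)
        assert s.n_epochs_averaged == len(events)
        assert s.epoch_length == pytest.approx(1.8 * 1.024, abs=1 / FS)
        assert s.t0 == 0.0


class TestGainInvariance:
    def test_pulsation_signal_invariant_to_raw_gain(self):
        spec = SimSpec(forward=ComponentWave(1.0, 0.15, 0.05),
                       reflected=ComponentWave(0.5, 0.35, 0.07),
                       duration=30.0)
        channels, events = simulate_session(spec, n_channels=1)
        ch = channels[0]
        s1 = preprocess_channel(ch, events)
        s2 = preprocess_channel(ch.with_samples(3.7 * ch.samples), events)
        assert np.allclose(s1.samples, s2.samples, atol=1e-12)


class TestQualityControl:
    def _signal(self, samples, median_rr=1.0):
        return ArterialPulsationSignal(np.asarray(samples, float), FS,
                                       len(samples) / FS, 1, median_rr,
                                       channel_id="q")

    def test_centred_pulse_passes(self):
        n = int(1.8 * FS)
        t = np.arange(n) / FS
        pulse = (np.exp(-0.5 * ((t - 0.35) / 0.08) ** 2)
                 + np.exp(-0.5 * ((t - 1.35) / 0.08) ** 2))
        rep = quality_control(self._signal(pulse - pulse.mean()))
        assert rep.passed and rep.reasons == []

    def test_monotone_ramp_fails_pulse_shape(self):
        n = int(1.8 * FS)
        rep = quality_control(self._signal(np.linspace(0, 1, n)))
        assert not rep.passed
        assert "no-pulse-shape" in rep.reasons

    def test_pure_noise_fails_snr(self):
        rng = np.random.default_rng(5)
        n = int(1.8 * FS)
        rep = quality_control(self._signal(rng.normal(0, 1, n)))
        assert not rep.passed
        assert "low-snr" in rep.reasons

    def test_metrics_always_populated(self):
        n = int(1.8 * FS)
        rep = quality_control(self._signal(np.linspace(0, 1, n)))
        assert np.isfinite(rep.snr_db) or rep.snr_db == float("-inf")
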