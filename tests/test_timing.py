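"""Second-derivative fiducial detection, exclusion rules, subject TI."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirspulse.errors import ChannelExcluded, InsufficientDataError
from nirspulse.signals import ArterialPulsationSignal
from nirspulse.synthetic import (MORPHOLOGY_PRESETS, ComponentWave, SimSpec,
                                 ground_truth, simulate_pulse,
                                 simulate_session)
from nirspulse.preprocessing import preprocess_channel
from nirspulse.timing import (FiducialTimes, detect_fiducials, detect_t_refl,
                              detect_t_sys, exclude_channels,
                              second_derivative, subject_ti)

FS = 39.0625


def _signal(samples, fs=FS, median_rr=1.0):
    samples = np.asarray(samples, float)
    return ArterialPulsationSignal(samples, fs, len(samples) / fs, 1,
                                   median_rr, channel_id="t")


class TestSecondDerivative:
    def test_quadratic_gives_constant_curvature(self):
        t = np.arange(0, 1.8, 1 / FS)
        s2 = second_derivative(_signal(t ** 2), smooth=False)
        assert np.allclose(s2.samples[1:-1], 2.0, atol=1e-6)

    def test_sine_zero_crossings_match_closed_form(self):
        # s = sin(2*pi*t)  =>  s2 = -(2*pi)^2 sin(2*pi*t): same zeros
        t = np.arange(0, 1.8, 1 / FS)
        s2 = second_derivative(_signal(np.sin(2 * np.pi * t)), smooth=False)
        # the only sign change interior to the first cycle is at t = 0.5
        assert len(s2.zero_crossings) == 1
        assert s2.zero_crossings[0] == pytest.approx(0.5, abs=1 / FS)

    def test_constant_signal_has_no_crossings(self):
        s2 = second_derivative(_signal(np.ones(70)), smooth=False)
        assert len(s2.zero_crossings) == 0

    def test_too_short_cycle_rejected(self):
        with pytest.raises(InsufficientDataError):
            second_derivative(_signal(np.ones(3), median_rr=0.05))

    def test_crossing_times_strictly_increasing(self):
        sig, _ = simulate_pulse(MORPHOLOGY_PRESETS["distinct-peaks"])
        s2 = second_derivative(sig)
        assert np.all(np.diff(s2.zero_crossings) > 0)


class TestDetectTsys:
    def test_distinct_peak_uses_first_peak(self):
        sig, _ = simulate_pulse(MORPHOLOGY_PRESETS["distinct-peaks"])
        s2 = second_derivative(sig)
        t_sys = detect_t_sys(sig, s2)
        # the first s-peak comes before the second zero crossing
        assert t_sys < s2.zero_crossings[1]
        assert t_sys == pytest.approx(0.15, abs=1.5 / FS)

    def test_inflection_systole_uses_zc2(self):
        # dominant reflected peak: systole appears only as a rise inflection
        spec = dataclasses.replace(MORPHOLOGY_PRESETS["systolic-inflection"],
                                   duration=60.0)
        channels, events = simulate_session(spec, n_channels=1)
        s = preprocess_channel(channels[0], events)
        s2 = second_derivative(s)
        t_sys = detect_t_sys(s, s2)
        assert t_sys == pytest.approx(s2.zero_crossings[1], abs=1e-9)
        assert t_sys < spec.reflected.peak_time

    def test_forward_only_bell_recovered(self):
        spec = SimSpec(forward=ComponentWave(1.0, 0.30, 0.05),
                       reflected=ComponentWave(1e-6, 0.90, 0.07))
        sig, _ = simulate_pulse(spec)
        s2 = second_derivative(sig, smooth=False)
        assert detect_t_sys(sig, s2) == pytest.approx(0.30, abs=1.0 / FS)

    def test_fewer_than_four_crossings_excluded(self):
        t = np.arange(0, 1.8, 1 / FS)
        sig = _signal(np.sin(np.pi * t / 1.8))  # single arch: 0 crossings
        s2 = second_derivative(sig, smooth=False)
        with pytest.raises(ChannelExcluded) as err:
            detect_t_sys(sig, s2)
        assert err.value.rule == "zc<4"


class TestDetectTrefl:
    def test_separated_bells_positive_peak_mode(self):
        sig, gt = simulate_pulse(MORPHOLOGY_PRESETS["distinct-peaks"])
        s2 = second_derivative(sig)
        t_refl, mode = detect_t_refl(sig, s2)
        assert mode == "positive_peak"
        assert abs(t_refl - gt.t_refl_true) <= 2 / FS

    def test_shoulder_uses_s2_minimum(self):
        spec = dataclasses.replace(MORPHOLOGY_PRESETS["shoulder"],
                                   duration=60.0)
        channels, events = simulate_session(spec, n_channels=1)
        s = preprocess_channel(channels[0], events)
        s2 = second_derivative(s)
        _, mode = detect_t_refl(s, s2)
        assert mode == "s2_minimum"

    def test_negative_valued_maxima_fall_back_to_s2_minimum(self):
        # pulse shifted down so every local max in the window is negative
        sig, _ = simulate_pulse(MORPHOLOGY_PRESETS["distinct-peaks"])
        shifted = _signal(sig.samples - 2.0)
        s2 = second_derivative(shifted)
        _, mode = detect_t_refl(shifted, s2)
        assert mode == "s2_minimum"


class TestExcludeChannels:
    @staticmethod
    def _fid(t_sys, t_refl, cid="c"):
        return FiducialTimes(t_sys, t_refl, "positive_peak", cid)

    def test_fixed_thresholds(self):
        fids = [self._fid(0.120, 0.300, "early"),
                self._fid(0.200, 0.510, "late"),
                self._fid(0.200, 0.400, "ok1"),
                self._fid(0.210, 0.410, "ok2")]
        kept, log = exclude_channels(fids)
        assert {f.channel_id for f in kept} == {"ok1", "ok2"}
        rules = {r.channel_id: r.rule for r in log}
        assert rules["early"] == "tsys<125ms"
        assert rules["late"] == "trefl>500ms"

    @staticmethod
    def _clustered(outlier=True):
        # two tight clusters: every inlier sits well inside mean +/- 1.5 SD
        fids = [TestExcludeChannels._fid(0.195, 0.395, f"a{i}")
                for i in range(10)]
        fids += [TestExcludeChannels._fid(0.205, 0.405, f"b{i}")
                 for i in range(10)]
        if outlier:
            fids.append(TestExcludeChannels._fid(0.260, 0.460, "outlier"))
        return fids

    def test_sd_fence_removes_outlier(self):
        fids = self._clustered()
        kept, log = exclude_channels(fids)
        # brute-force check of the fence on the constructed set
        vals = np.array([f.t_sys for f in fids])
        mean, sd = vals.mean(), vals.std(ddof=1)
        assert 0.260 > mean + 1.5 * sd          # planted value is outside
        assert all(abs(f.t_sys - mean) <= 1.5 * sd for f in kept)
        assert {r.channel_id for r in log} == {"outlier"}
        assert log[0].rule == "tsys-outlier"
        assert len(kept) == 20

    def test_sd_stats_computed_after_fixed_thresholds(self):
        # a gross threshold violation must not inflate the SD fence
        fids = [self._fid(0.200 + 0.001 * i, 0.400, f"c{i}")
                for i in range(10)]
        fids.append(self._fid(0.200, 0.900, "gross"))
        kept, log = exclude_channels(fids)
        assert {r.rule for r in log} == {"trefl>500ms"}
        assert len(kept) == 10

    def test_idempotent_on_clustered_sets(self):
        once, _ = exclude_channels(self._clustered())
        twice, log2 = exclude_channels(once)
        assert twice == once and log2 == []

    def test_empty_input_ok(self):
        kept, log = exclude_channels([])
        assert kept == [] and log == []


class TestSubjectTI:
    @staticmethod
    def _fids(deltas):
        return [FiducialTimes(0.2, 0.2 + d, "positive_peak", f"c{i}")
                for i, d in enumerate(deltas)]

    def test_constant_delta(self):
        res = subject_ti(self._fids([0.20] * 10))
        assert res.ti == pytest.approx(5.0)
        assert res.n_channels_used == 10

    def test_mean_of_inverses_not_inverse_of_mean(self):
        res = subject_ti(self._fids([0.20, 0.25] * 5))
        assert res.ti == pytest.approx((5.0 + 4.0) / 2)

    def test_nine_channels_no_ti(self):
        res = subject_ti(self._fids([0.2] * 9))
        assert res.ti is None
        assert res.n_channels_used == 9


class TestInvariances:
    @settings(max_examples=10, deadline=None)
    @given(st.sampled_from([0.1, 1.0, 10.0]))
    def test_amplitude_scaling_leaves_fiducials_unchanged(self, c):
        sig, _ = simulate_pulse(MORPHOLOGY_PRESETS["distinct-peaks"])
        f0 = detect_fiducials(sig)
        f1 = detect_fiducials(sig.with_samples(c * sig.samples))
        assert f1.t_sys == f0.t_sys
        assert f1.t_refl == f0.t_refl
        assert f1.refl_mode == f0.refl_mode

    def test_time_origin_shift_leaves_ti_unchanged(self):
        # translating s (and its R-peak origin) by whole samples shifts both
        # fiducials equally, so the reflection time and TI are exact-invariant
        spec = dataclasses.replace(MORPHOLOGY_PRESETS["distinct-peaks"],
                                   duration=2.3)
        sig, _ = simulate_pulse(spec)
        f0 = detect_fiducials(sig, smooth=False)
        k = 4
        shifted = ArterialPulsationSignal(
            np.concatenate([np.zeros(k), sig.samples]), sig.fs,
            sig.epoch_length + k / sig.fs, 1, sig.median_rr,
            channel_id="shifted")
        f1 = detect_fiducials(shifted, smooth=False)
        assert f1.t_sys == pytest.approx(f0.t_sys + k / sig.fs, abs=1e-9)
        assert f1.reflection_time == pytest.approx(f0.reflection_time,
                                                   abs=1e-9)

    def test_recovery_on_presets_zero_noise(self):
        for name, spec in MORPHOLOGY_PRESETS.items():
            sig, gt = simulate_pulse(spec)
            f = detect_fiducials(sig)
            assert abs(f.reflection_time - gt.delta_true) <= 2 / spec.fs, name
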