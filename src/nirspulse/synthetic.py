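"""Synthetic composite arterial pulsation signals with known ground truth.

A beat is modelled phenomenologically as the sum of an incident
forward-travelling wave, a reflected wave returning from the periphery, an
optional re-reflected wave and an optional negative dicrotic-notch component.
Each component is a bell; the default is an asymmetric gamma-like bell (fast
rise, slow decay) because arterial pulses are skewed, with a pure Gaussian
option. No transmission-line or Windkessel physics is implied — the
components are descriptive shapes whose peak times are the ground truth
against which fiducial detection is validated.

Sessions repeat the composite beat at jittered heart periods and emit raw
intensity traces with acquisition polarity (systole = intensity trough), so
the full preprocessing chain, including the sign flip, is exercised.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .signals import ArterialPulsationSignal, RawChannel, RPeakEvents

#: Shape constant of the gamma-like bell (larger = more symmetric); the
#: asymmetric fast-rise/slow-decay silhouette matches arterial pulses.
GAMMA_SHAPE = 4.0

#: Fractional intensity modulation of the raw trace by a unit-amplitude pulse.
PULSE_MODULATION = 0.01

#: Baseline raw intensity level (arbitrary units).
BASELINE_INTENSITY = 100.0


@dataclass(frozen=True)
class ComponentWave:
    """One bell-shaped wave component of the composite pulse.

    Parameters
    ----------
    amplitude:
        Peak amplitude (dimensionless). Negative only for a notch component.
    peak_time:
        Time of the component's maximum, in seconds from pulse onset.
    width:
        Temporal scale in seconds (standard-deviation-like).
    shape:
        ``"gamma_like"`` (default, skewed) or ``"gaussian"``.
    """

    amplitude: float
    peak_time: float
    width: float
    shape: str = "gamma_like"

    def __post_init__(self):
        if self.width <= 0:
            raise InvalidSpecError("component width must be > 0")
        if not np.isfinite(self.peak_time) or self.peak_time < 0:
            raise InvalidSpecError("component peak_time must be finite and >= 0")
        if self.shape not in ("gaussian", "gamma_like"):
            raise InvalidSpecError(f"unknown component shape {self.shape!r}")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Component amplitude at times ``t`` (seconds from pulse onset)."""
        t = np.asarray(t, dtype=float)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(
                -0.5 * ((t - self.peak_time) / self.width) ** 2)
        # gamma-like bell: mode exactly at peak_time, value exactly amplitude
        k = GAMMA_SHAPE
        theta = self.width / np.sqrt(k)
        onset = self.peak_time - (k - 1.0) * theta
        x = np.clip(t - onset, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.amplitude * np.exp(
                (k - 1.0) * np.log(np.where(x > 0, x / ((k - 1.0) * theta), 1.0))
                + (k - 1.0) - x / theta)
        out = np.where(x <= 0, 0.0, out)
        return out


@dataclass(frozen=True)
class SimSpec:
    """Full parameterisation of a simulated pulse / recording session."""

    forward: ComponentWave
    reflected: ComponentWave
    re_reflected: ComponentWave | None = None
    notch: ComponentWave | None = None
    noise_sd: float = 0.0
    fs: float = 39.0625
    duration: float = 1.8
    heart_period_mean: float = 1.0
    heart_period_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.reflected.peak_time <= self.forward.peak_time:
            raise InvalidSpecError(
                "reflected wave must peak after the forward wave")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.fs < 2 * 5.0:
            raise InvalidSpecError(
                "fs must be >= 10 Hz so the 0.5-5 Hz passband is representable")
        if self.duration <= 0 or self.heart_period_mean <= 0:
            raise InvalidSpecError("duration and heart period must be > 0")
        if self.heart_period_jitter_sd < 0:
            raise InvalidSpecError("heart_period_jitter_sd must be >= 0")
        if self.forward.amplitude <= 0 or self.reflected.amplitude <= 0:
            raise InvalidSpecError(
                "forward and reflected amplitudes must be > 0")
        if self.notch is not None and self.notch.amplitude > 0:
            raise InvalidSpecError("notch amplitude must be negative")

    @property
    def components(self) -> list[ComponentWave]:
        comps = [self.forward, self.reflected]
        if self.re_reflected is not None:
            comps.append(self.re_reflected)
        if self.notch is not None:
            comps.append(self.notch)
        return comps

    def composite(self, t: np.ndarray) -> np.ndarray:
        """Noise-free composite waveform at times ``t`` from pulse onset."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.components:
            out += c.evaluate(t)
        return out


@dataclass(frozen=True)
class GroundTruth:
    """True fiducial times of a simulated pulse, seconds from pulse onset."""

    t_sys_true: float
    t_refl_true: float

    @property
    def delta_true(self) -> float:
        return self.t_refl_true - self.t_sys_true


def _component_argmax(spec: SimSpec, component: ComponentWave,
                      dense_dt: float = 1e-4) -> float:
    """Argmax time of the noise-free composite near one component's peak.

    Truth is defined on the composite restricted to +/- one component width
    around the component's own peak, so that under heavy overlap the target
    is the composite's local extremum rather than the isolated bell's.
    """
    t = np.arange(component.peak_time - component.width,
                  component.peak_time + component.width + dense_dt, dense_dt)
    return float(t[np.argmax(spec.composite(t))])


def ground_truth(spec: SimSpec) -> GroundTruth:
    gt = GroundTruth(_component_argmax(spec, spec.forward),
                     _component_argmax(spec, spec.reflected))
    if gt.delta_true <= 0:
        raise InvalidSpecError(
            "components overlap so heavily that ground truth collapses")
    return gt


def simulate_pulse(spec: SimSpec) -> tuple[ArterialPulsationSignal, GroundTruth]:
    """Simulate one epoch-length composite pulse plus its ground truth.

    The waveform is the pointwise sum of the component waves over
    ``[0, spec.duration]`` plus i.i.d. Gaussian noise of SD ``spec.noise_sd``.
    """
    n = int(np.floor(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    samples = spec.composite(t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        samples = samples + rng.normal(0.0, spec.noise_sd, size=n)
    sig = ArterialPulsationSignal(
        samples=samples, fs=spec.fs, epoch_length=spec.duration,
        n_epochs_averaged=1, median_rr=spec.heart_period_mean,
        channel_id="sim")
    return sig, ground_truth(spec)


def _r_peak_times(spec: SimSpec, rng: np.random.Generator,
                  start: float = 0.3) -> np.ndarray:
    times = [start]
    while True:
        period = spec.heart_period_mean
        if spec.heart_period_jitter_sd > 0:
            period += rng.normal(0.0, spec.heart_period_jitter_sd)
        period = max(period, 0.3 * spec.heart_period_mean)
        nxt = times[-1] + period
        if nxt > spec.duration:
            break
        times.append(nxt)
    return np.asarray(times)


def simulate_session(
    spec: SimSpec,
    n_channels: int,
    r_peak_offset: float = 0.0,
    sd_range: tuple[float, float] = (25.0, 50.0),
    invert: bool = True,
) -> tuple[list[RawChannel], RPeakEvents]:
    """Simulate a multi-channel raw recording with R-peak events.

    Beats are repeated at jittered heart periods; each channel is the
    baseline intensity modulated by the pulse train (trough at systole when
    ``invert`` is true, matching acquisition polarity) plus white noise.
    R-peak times precede each pulse onset by ``r_peak_offset`` seconds.
    Source-detector distances are spaced evenly over ``sd_range`` (mm).
    """
    if n_channels < 1:
        raise InvalidSpecError("n_channels must be >= 1")
    if spec.duration < 3 * spec.heart_period_mean:
        raise InvalidSpecError("session duration must cover >= 3 heart periods")
    rng = np.random.default_rng(spec.seed)
    r_times = _r_peak_times(spec, rng)
    n = int(np.floor(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs

    # pulse train shared by all channels (gain varies per channel)
    pulse = np.zeros(n)
    half_support = 8.0 * max(c.width for c in spec.components)
    for r in r_times:
        onset = r + r_peak_offset
        latest = max(c.peak_time for c in spec.components)
        i0 = max(int((onset - 0.1) * spec.fs), 0)
        i1 = min(int((onset + latest + half_support) * spec.fs) + 1, n)
        if i1 > i0:
            pulse[i0:i1] += spec.composite(t[i0:i1] - onset)

    sign = -1.0 if invert else 1.0
    distances = np.linspace(sd_range[0], sd_range[1], n_channels)
    channels = []
    for ch in range(n_channels):
        gain = rng.uniform(0.9, 1.1)
        noise = (rng.normal(0.0, spec.noise_sd, size=n)
                 if spec.noise_sd > 0 else 0.0)
        raw = BASELINE_INTENSITY * (
            1.0 + sign * PULSE_MODULATION * (gain * pulse + noise))
        channels.append(RawChannel(
            samples=raw, fs=spec.fs, channel_id=f"ch{ch:02d}",
            sd_distance=float(distances[ch])))
    return channels, RPeakEvents(r_times)


# --- morphology presets -----------------------------------------------------
#
# Three documented presets covering the canonical pulse morphologies:
#   distinct-peaks       systolic and reflected peaks both visible as peaks
#   shoulder             reflected wave visible only as a shoulder/inflection
#   systolic-inflection  dominant reflected peak; systole is an inflection on
#                        the rising edge
# Parameters are package choices (amplitudes dimensionless, times in seconds).

MORPHOLOGY_PRESETS: dict[str, SimSpec] = {
    "distinct-peaks": SimSpec(
        forward=ComponentWave(1.0, 0.15, 0.05),
        reflected=ComponentWave(0.55, 0.40, 0.07),
        re_reflected=ComponentWave(0.28, 0.65, 0.09),
    ),
    "shoulder": SimSpec(
        forward=ComponentWave(1.0, 0.15, 0.05),
        reflected=ComponentWave(0.45, 0.32, 0.08),
        re_reflected=ComponentWave(0.25, 0.55, 0.09),
    ),
    "systolic-inflection": SimSpec(
        forward=ComponentWave(0.45, 0.14, 0.05),
        reflected=ComponentWave(1.0, 0.30, 0.08),
        re_reflected=ComponentWave(0.30, 0.60, 0.10),
    ),
}

#: Base waveform of the simulated cohort. The reflected wave's delay and
#: amplitude vary with the synthetic age covariate; the broad re-reflected
#: mound is fixed in late systole/early diastole and fills the relaxation
#: segment the way peripheral re-reflections do in vivo.
COHORT_FORWARD = ComponentWave(1.0, 0.15, 0.05)
COHORT_REFLECTED_WIDTH = 0.08
COHORT_RE_REFLECTED = ComponentWave(0.35, 0.60, 0.12)


def _reflected_amplitude(delta: float) -> float:
    """Reflected-wave amplitude for a given reflection delay.

    Compliant (young) vasculature shows a distinct late reflected bump;
    with stiffening the reflection arrives earlier and fuses with systole,
    so its standalone amplitude contribution is smaller.
    """
    return float(np.clip(0.45 + (delta - 0.10) * (0.25 / 0.15), 0.40, 0.75))


def linear_gradient(age: float, age_range: tuple[float, float],
                    delta_range: tuple[float, float]) -> float:
    """Linearly interpolate reflection time (s) for an age (years)."""
    a0, a1 = age_range
    d0, d1 = delta_range
    if a1 == a0:
        raise InvalidSpecError("degenerate age range")
    frac = (age - a0) / (a1 - a0)
    return d0 + frac * (d1 - d0)


def cohort_generator(
    n_subjects: int,
    stiffness_gradient: dict | None = None,
    seed: int = 0,
    base: SimSpec | None = None,
    noise_sd: float = 0.1,
    duration: float = 60.0,
) -> tuple[list[SimSpec], pd.DataFrame]:
    """Generate per-subject simulation specs with an age-linked gradient.

    The reflection delay (reflected minus forward peak time) decreases
    linearly with a synthetic age covariate, emulating arterial stiffening,
    and the reflected amplitude shrinks as the wave fuses into systole.
    Demographic covariates (sex, BMI, resting heart rate, activity score)
    are drawn independently so the fitness model has plausible inputs.

    Returns the spec list and a covariate table with one row per subject.
    """
    if n_subjects < 3:
        raise InvalidSpecError("cohort needs n_subjects >= 3")
    grad = {"age_range": (20.0, 70.0), "delta_range": (0.25, 0.10)}
    if stiffness_gradient:
        grad.update(stiffness_gradient)
    d0, d1 = grad["delta_range"]
    if d0 == d1:
        warnings.warn("degenerate stiffness gradient: zero delta variance",
                      stacklevel=2)
    fwd = base.forward if base is not None else COHORT_FORWARD

    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(*grad["age_range"], size=n_subjects))
    specs, rows = [], []
    for i, age in enumerate(ages):
        delta = linear_gradient(age, grad["age_range"], grad["delta_range"])
        refl = ComponentWave(_reflected_amplitude(delta),
                             fwd.peak_time + delta, COHORT_REFLECTED_WIDTH)
        hp = float(rng.uniform(0.75, 1.0))
        spec = SimSpec(
            forward=fwd, reflected=refl, re_reflected=COHORT_RE_REFLECTED,
            noise_sd=noise_sd, duration=duration, heart_period_mean=hp,
            heart_period_jitter_sd=0.02,
            seed=int(rng.integers(0, 2**31 - 1)))
        specs.append(spec)
        rows.append({
            "subject": f"sub{i:03d}",
            "age": float(age),
            "sex": "M" if rng.random() < 0.5 else "F",
            "bmi": float(rng.normal(25.0, 3.0)),
            "resting_hr": float(np.clip(rng.normal(64.0, 7.0), 45, 95)),
            "activity_score": int(rng.integers(0, 8)),
            "delta_true": float(delta),
        })
    return specs, pd.DataFrame(rows)
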