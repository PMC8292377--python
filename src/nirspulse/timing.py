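"""Timing index of cerebrovascular stiffness from second-derivative fiducials.

The reflection time — the interval between the systolic (incident) peak and
the reflected-wave peak of the arterial pulsation signal — shortens as
arteries stiffen. The timing index is its reciprocal, TI = 1/(t_refl - t_sys),
so larger TI means stiffer vasculature.

Fiducials are located on the first cardiac cycle of *s* via the zero
crossings of its second derivative s2 (the approach long used on pressure
and PPG waveforms to find peaks and inflection points):

* t_sys = min(t_p1, t_zc2): the earlier of the first local maximum of *s*
  and the second s2 zero crossing. When the systolic peak survives only as
  an inflection on the rising edge of a dominant reflected wave, t_zc2
  lands on that inflection.
* t_refl is searched only between the third and fourth zero crossings: the
  first positive local maximum of *s* there if one exists (a visible
  reflected peak), otherwise the s2 minimum in the window (the point of
  greatest concavity, marking a reflected shoulder).

Channels with fewer than four s2 zero crossings are excluded, as are
fiducials failing the fixed thresholds (t_sys < 125 ms, t_refl > 500 ms,
measured from the R peak) or lying outside the per-subject mean +/- 1.5 SD.
A subject-level TI is reported only when at least ten channels survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ChannelExcluded, InsufficientDataError
from .signals import ArterialPulsationSignal

#: Fixed exclusion thresholds, seconds from the R peak.
T_SYS_MIN_DEFAULT = 0.125
T_REFL_MAX_DEFAULT = 0.500

#: Outlier fence in units of the per-subject standard deviation.
SD_FENCE_DEFAULT = 1.5

#: Minimum surviving channels for a subject-level TI ("ten or more").
MIN_CHANNELS_TI = 10

#: Savitzky-Golay pre-smoothing defaults (window samples, polynomial order).
SMOOTH_WINDOW_DEFAULT = 7
SMOOTH_ORDER_DEFAULT = 3


@dataclass
class SecondDerivative:
    """Second derivative of *s* over its first cardiac cycle."""

    samples: np.ndarray          # d2s/dt2, first-cycle samples
    fs: float
    zero_crossings: np.ndarray   # ordered crossing times, seconds
    smoothing_applied: bool

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class FiducialTimes:
    """Detected (t_sys, t_refl) for one channel, seconds from the R peak."""

    t_sys: float
    t_refl: float
    refl_mode: str               # "positive_peak" | "s2_minimum"
    channel_id: str = ""

    def __post_init__(self):
        if not (0 <= self.t_sys < self.t_refl):
            raise ValueError("need 0 <= t_sys < t_refl")
        if self.refl_mode not in ("positive_peak", "s2_minimum"):
            raise ValueError(f"unknown refl_mode {self.refl_mode!r}")

    @property
    def reflection_time(self) -> float:
        return self.t_refl - self.t_sys


@dataclass
class ExclusionRecord:
    """One audited channel removal."""

    channel_id: str
    rule: str
    value: float


@dataclass
class SubjectTI:
    """Per-subject timing index; ``ti`` is None when < 10 channels remain."""

    ti: float | None
    n_channels_used: int
    excluded: dict = field(default_factory=dict)


def _zero_crossing_times(x: np.ndarray, fs: float) -> np.ndarray:
    """Sign-change times of ``x`` with linear interpolation.

    Exact zeros belong to the crossing at that sample: a run of zeros
    between opposite signs yields one crossing at the first zero sample;
    between equal signs it yields none.
    """
    sign = np.sign(x)
    nz = np.nonzero(sign)[0]
    times = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] == sign[b]:
            continue
        if b == a + 1:
            t = (a + x[a] / (x[a] - x[b])) / fs
        else:  # zeros in between: crossing at the first zero sample
            t = (a + 1) / fs
        times.append(t)
    return np.asarray(times)


def second_derivative(s: ArterialPulsationSignal, smooth: bool = True,
                      window: int = SMOOTH_WINDOW_DEFAULT,
                      order: int = SMOOTH_ORDER_DEFAULT) -> SecondDerivative:
    """Central-difference second derivative of the first cardiac cycle.

    Optional Savitzky-Golay smoothing precedes differencing: raw second
    differences of a 39 Hz trace ring on residual noise. The returned
    samples cover the first cycle; endpoint values replicate their
    neighbours so the array length matches the cycle.
    """
    cycle = s.first_cycle()
    if len(cycle) < 5:
        raise InsufficientDataError("first cardiac cycle has < 5 samples")
    y = cycle
    applied = False
    if smooth and len(cycle) >= window and window > order:
        y = sps.savgol_filter(cycle, window, order)
        applied = True
    d2 = np.empty_like(y)
    d2[1:-1] = (y[2:] - 2 * y[1:-1] + y[:-2]) * s.fs ** 2
    d2[0], d2[-1] = d2[1], d2[-2]
    zc = _zero_crossing_times(d2[1:-1], s.fs) + 1.0 / s.fs
    return SecondDerivative(samples=d2, fs=s.fs, zero_crossings=zc,
                            smoothing_applied=applied)


def _local_maxima(cycle: np.ndarray) -> np.ndarray:
    """Indices of local maxima, plateaus resolved to their left edge."""
    peaks, props = sps.find_peaks(cycle, plateau_size=1)
    return np.asarray([int(le) for le in props["left_edges"]], dtype=int)


def detect_t_sys(s: ArterialPulsationSignal, s2: SecondDerivative) -> float:
    """t_sys = min(t_p1, t_zc2) on the first cardiac cycle."""
    if len(s2.zero_crossings) < 4:
        raise ChannelExcluded("zc<4", "fewer than 4 second-derivative "
                              "zero crossings in the first cycle")
    cycle = s.first_cycle()
    peaks = _local_maxima(cycle)
    if len(peaks) == 0:
        raise ChannelExcluded("no-peak", "no local maximum in first cycle")
    t_p1 = peaks[0] / s.fs
    t_zc2 = float(s2.zero_crossings[1])
    return float(min(t_p1, t_zc2))


def detect_t_refl(s: ArterialPulsationSignal,
                  s2: SecondDerivative) -> tuple[float, str]:
    """Reflected-wave time within the (t_zc3, t_zc4) window.

    Returns the first positive-valued local maximum of *s* in the open
    window if one exists (mode ``positive_peak``), otherwise the time of
    the s2 minimum there (mode ``s2_minimum``).
    """
    if len(s2.zero_crossings) < 4:
        raise ChannelExcluded("zc<4", "fewer than 4 second-derivative "
                              "zero crossings in the first cycle")
    t_zc3, t_zc4 = float(s2.zero_crossings[2]), float(s2.zero_crossings[3])
    if t_zc4 <= t_zc3:
        raise ChannelExcluded("bad-window", "empty (t_zc3, t_zc4) window")
    cycle = s.first_cycle()
    peaks = _local_maxima(cycle)
    peak_times = peaks / s.fs
    in_window = (peak_times > t_zc3) & (peak_times < t_zc4)
    positive = in_window & (cycle[peaks] > 0)
    if positive.any():
        return float(peak_times[positive][0]), "positive_peak"
    # s2 minimum restricted to the open window
    idx = np.arange(len(s2.samples))
    t = idx / s.fs
    mask = (t > t_zc3) & (t < t_zc4)
    if not mask.any():
        raise ChannelExcluded("bad-window", "window narrower than one sample")
    sub = np.where(mask)[0]
    t_min = sub[np.argmin(s2.samples[sub])] / s.fs
    return float(t_min), "s2_minimum"


def detect_fiducials(s: ArterialPulsationSignal,
                     smooth: bool = True) -> FiducialTimes:
    """Run the full second-derivative fiducial detection on one channel."""
    s2 = second_derivative(s, smooth=smooth)
    t_sys = detect_t_sys(s, s2)
    t_refl, mode = detect_t_refl(s, s2)
    if t_refl <= t_sys:
        raise ChannelExcluded("refl<=sys",
                              "reflected fiducial not after systolic")
    return FiducialTimes(t_sys=t_sys, t_refl=t_refl, refl_mode=mode,
                         channel_id=s.channel_id)


def exclude_channels(
    fiducials: list[FiducialTimes],
    t_sys_min: float = T_SYS_MIN_DEFAULT,
    t_refl_max: float = T_REFL_MAX_DEFAULT,
    sd_fence: float = SD_FENCE_DEFAULT,
) -> tuple[list[FiducialTimes], list[ExclusionRecord]]:
    """Apply the fixed-threshold and mean +/- 1.5 SD exclusion rules.

    Fixed thresholds first; the per-subject mean and SD of t_sys and t_refl
    are then computed once over the survivors and channels outside
    mean +/- ``sd_fence`` * SD for either statistic are removed (single
    pass). Every removal is logged with its rule identifier.
    """
    log: list[ExclusionRecord] = []
    survivors = []
    for f in fiducials:
        if f.t_sys < t_sys_min:
            log.append(ExclusionRecord(f.channel_id, "tsys<125ms", f.t_sys))
        elif f.t_refl > t_refl_max:
            log.append(ExclusionRecord(f.channel_id, "trefl>500ms", f.t_refl))
        else:
            survivors.append(f)
    if len(survivors) >= 2:
        for attr, rule in (("t_sys", "tsys-outlier"), ("t_refl", "trefl-outlier")):
            vals = np.asarray([getattr(f, attr) for f in survivors])
            mean, sd = vals.mean(), vals.std(ddof=1)
            lo, hi = mean - sd_fence * sd, mean + sd_fence * sd
            kept = []
            for f in survivors:
                v = getattr(f, attr)
                if lo <= v <= hi:
                    kept.append(f)
                else:
                    log.append(ExclusionRecord(f.channel_id, rule, v))
            survivors = kept
    return survivors, log


def subject_ti(fiducials: list[FiducialTimes],
               min_channels: int = MIN_CHANNELS_TI,
               exclusion_log: list[ExclusionRecord] | None = None) -> SubjectTI:
    """Average the per-channel timing indices 1/(t_refl - t_sys).

    A subject-level TI exists only when ``min_channels`` or more channels
    survive exclusion (mean of inverses, not inverse of the mean delta).
    """
    counts: dict[str, int] = {}
    for rec in exclusion_log or []:
        counts[rec.rule] = counts.get(rec.rule, 0) + 1
    if len(fiducials) < min_channels:
        return SubjectTI(ti=None, n_channels_used=len(fiducials),
                         excluded=counts)
    tis = [1.0 / f.reflection_time for f in fiducials]
    return SubjectTI(ti=float(np.mean(tis)), n_channels_used=len(fiducials),
                     excluded=counts)
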