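"""Pulse relaxation function (PReFx), an area-ratio compliance index.

On the two-cycle arterial pulsation signal *s*, the diastolic minima of the
first and second cardiac cycles (t_D1, t_D2) and the first local maximum
after t_D1 (t_S, nominally the systolic peak) define the systolic-to-
diastolic relaxation segment. With

    A = area enclosed between *s* and the s(t_D2) level over [t_S, t_D2]
    B = area of the rectangle with (t_S, s(t_S)) and (t_D2, s(t_D2)) at its
        diagonal ends

the index is PReFx = A/B - 0.5. A linear decline gives exactly 0; bulging
(concave) relaxation — a late, distinct reflected wave, i.e. compliant
arteries — gives positive values; sagging (convex) decline gives negative
values. The known failure mode is t_S landing on the reflected peak when
the true systolic peak is only an inflection; such channels are flagged by
comparing t_S with the second-derivative systolic fiducial and removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ChannelExcluded, DegenerateGeometryError
from .signals import ArterialPulsationSignal
from .timing import _local_maxima

#: Channels with PReFx outside this closed interval are rejected.
PREFX_INTERVAL_DEFAULT = (-0.1, 0.4)

#: Subject-level PReFx needs strictly more than this many channels.
MIN_CHANNELS_PREFX = 10


@dataclass
class PrefxFiducials:
    """Diastolic minima of cycles 1 and 2 and the intervening maximum."""

    t_d1: float
    t_s: float
    t_d2: float
    s_d1: float
    s_s: float
    s_d2: float

    def __post_init__(self):
        if not (self.t_d1 < self.t_s < self.t_d2):
            raise ValueError("need t_D1 < t_S < t_D2")
        if not (self.s_s > self.s_d2):
            raise ValueError("need s(t_S) > s(t_D2)")


@dataclass
class PrefxValue:
    """PReFx for one channel with its area components."""

    value: float
    area_a: float
    area_b: float
    channel_id: str = ""
    flagged_reflected_as_systole: bool = False


@dataclass
class PrefxExclusion:
    channel_id: str
    rule: str
    value: float


def prefx_fiducials(s: ArterialPulsationSignal) -> PrefxFiducials:
    """Locate t_D1, t_S, t_D2 on a two-cycle epoch.

    Cycle boundaries sit at multiples of the median R-R interval within the
    epoch; the second cycle may be partial but must contain its diastolic
    minimum before the epoch ends.
    """
    n_cycle = int(round(s.median_rr * s.fs))
    x = s.samples
    if len(x) <= n_cycle + 2:
        raise ChannelExcluded("one-cycle",
                              "epoch does not reach the second cardiac cycle")
    cycle1 = x[:n_cycle]
    cycle2 = x[n_cycle:min(2 * n_cycle, len(x))]
    i_d1 = int(np.argmin(cycle1))
    i_d2 = n_cycle + int(np.argmin(cycle2))
    peaks = _local_maxima(x)
    after = peaks[peaks > i_d1]
    if len(after) == 0:
        raise ChannelExcluded("no-peak", "no local maximum after t_D1")
    i_s = int(after[0])
    if not (i_d1 < i_s < i_d2):
        raise ChannelExcluded("one-cycle",
                              "fiducial ordering t_D1 < t_S < t_D2 violated")
    if not (x[i_s] > x[i_d2]):
        raise ChannelExcluded("one-cycle", "s(t_S) does not exceed s(t_D2)")
    return PrefxFiducials(
        t_d1=i_d1 / s.fs, t_s=i_s / s.fs, t_d2=i_d2 / s.fs,
        s_d1=float(x[i_d1]), s_s=float(x[i_s]), s_d2=float(x[i_d2]))


def prefx_value(s: ArterialPulsationSignal, f: PrefxFiducials,
                channel_id: str | None = None) -> PrefxValue:
    """PReFx = A/B - 0.5 by trapezoidal integration at native sampling."""
    i_s = int(round(f.t_s * s.fs))
    i_d2 = int(round(f.t_d2 * s.fs))
    seg = s.samples[i_s:i_d2 + 1]
    area_a = float(np.trapezoid(seg - f.s_d2, dx=1.0 / s.fs))
    area_b = (f.t_d2 - f.t_s) * (f.s_s - f.s_d2)
    if area_b <= 0:
        raise DegenerateGeometryError("PReFx rectangle has area <= 0")
    return PrefxValue(value=area_a / area_b - 0.5, area_a=area_a,
                      area_b=float(area_b),
                      channel_id=channel_id or s.channel_id)


def flag_reflected_as_systole(f: PrefxFiducials, t_sys: float,
                              fs: float, tol_samples: int = 1) -> bool:
    """Flag a channel whose t_S disagrees with the second-derivative systole.

    Automated stand-in for the manual screen: when the timing detector's
    t_sys precedes t_S by more than ``tol_samples``, the PReFx peak-picker
    chose a later (reflected) peak as the systolic point.
    """
    return abs(f.t_s - t_sys) > tol_samples / fs


def prefx_channel(s: ArterialPulsationSignal,
                  t_sys: float | None = None) -> PrefxValue:
    """Fiducials + value + reflected-as-systole flag for one channel."""
    f = prefx_fiducials(s)
    v = prefx_value(s, f)
    if t_sys is not None:
        v.flagged_reflected_as_systole = flag_reflected_as_systole(
            f, t_sys, s.fs)
    return v


def prefx_screen(
    values: list[PrefxValue],
    interval: tuple[float, float] = PREFX_INTERVAL_DEFAULT,
) -> tuple[list[PrefxValue], list[PrefxExclusion]]:
    """Reject channels outside the closed PReFx interval, then flagged ones."""
    lo, hi = interval
    log: list[PrefxExclusion] = []
    kept = []
    for v in values:
        if not (lo <= v.value <= hi):
            log.append(PrefxExclusion(v.channel_id, "prefx-range", v.value))
        elif v.flagged_reflected_as_systole:
            log.append(PrefxExclusion(v.channel_id, "refl-as-sys", v.value))
        else:
            kept.append(v)
    return kept, log


def subject_prefx(values: list[PrefxValue],
                  min_channels: int = MIN_CHANNELS_PREFX) -> float | None:
    """Mean channel PReFx when strictly more than ``min_channels`` remain."""
    if len(values) <= min_channels:
        return None
    return float(np.mean([v.value for v in values]))
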