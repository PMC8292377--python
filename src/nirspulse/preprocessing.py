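"""Raw optical channels -> arterial pulsation signals.

Fixed pipeline order: distance selection -> normalisation (divide by mean)
-> 0.5-5.0 Hz zero-phase band-pass -> R-peak-locked epoch averaging ->
sign flip -> automated pulse-shape screen. Each stage is individually
invocable; ``preprocess_channel`` composes them.

The band-pass is a 3rd-order Butterworth applied forward-backward
(``sosfiltfilt``): any phase distortion would bias the fiducial times that
are the package's core output, so zero phase is non-negotiable.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import (DegenerateChannelError, InsufficientDataError,
                     InvalidConfigError)
from .signals import (ArterialPulsationSignal, QualityReport, RawChannel,
                      RPeakEvents)

#: Default source-detector selection window (mm). The 25-50 mm preset is the
#: range most likely to produce usable cortical waveforms.
SD_WINDOW_DEFAULT = (20.0, 60.0)
SD_WINDOW_USABLE = (25.0, 50.0)

#: Cardiac band (Hz) capturing pulse dynamics while rejecting drift.
BAND_DEFAULT = (0.5, 5.0)

#: Epoch length as a multiple of the median R-R interval: long enough to
#: contain the diastolic minima of two consecutive cycles, short enough to
#: exclude a third.
EPOCH_FACTOR_DEFAULT = 1.8

#: Cardiac-band SNR floor (dB) for the quality screen.
SNR_FLOOR_DB_DEFAULT = 3.0


def select_channels(channels: list[RawChannel], min_mm: float = SD_WINDOW_DEFAULT[0],
                    max_mm: float = SD_WINDOW_DEFAULT[1]) -> list[RawChannel]:
    """Keep channels with min_mm <= source-detector distance <= max_mm."""
    if min_mm >= max_mm:
        raise InvalidConfigError("min_mm must be < max_mm")
    return [c for c in channels if min_mm <= c.sd_distance <= max_mm]


def normalize_channel(channel: RawChannel) -> RawChannel:
    """Divide the intensity trace by its mean (output mean = 1)."""
    mean = channel.samples.mean()
    if not np.isfinite(mean) or abs(mean) < 1e-12:
        raise DegenerateChannelError(
            f"channel {channel.channel_id}: mean intensity is zero")
    return channel.with_samples(channel.samples / mean)


def bandpass(channel: RawChannel, lo: float = BAND_DEFAULT[0],
             hi: float = BAND_DEFAULT[1], order: int = 3) -> RawChannel:
    """Zero-phase Butterworth band-pass; removes DC and drift."""
    nyq = channel.fs / 2.0
    if not (0 < lo < hi):
        raise InvalidConfigError("need 0 < lo < hi")
    if hi >= nyq:
        raise InvalidConfigError(
            f"band edge {hi} Hz is not below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=channel.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, channel.samples - channel.samples.mean())
    return channel.with_samples(filtered)


def epoch_average(channel: RawChannel, events: RPeakEvents,
                  epoch_length: float | None = None,
                  epoch_factor: float = EPOCH_FACTOR_DEFAULT,
                  ) -> ArterialPulsationSignal:
    """Average R-peak-locked epochs and flip the sign.

    Epochs start at the nearest sample to each R-peak time (no sub-sample
    interpolation) and are usable only if fully inside the recording. The
    average is negated so that systole, an intensity trough in the raw
    trace, becomes a positive peak in *s*.
    """
    if len(events) < 3:
        raise InsufficientDataError("need >= 3 R-peak events")
    median_rr = events.median_rr
    if epoch_length is None:
        epoch_length = epoch_factor * median_rr
    n_epoch = int(round(epoch_length * channel.fs))
    if n_epoch < 2:
        raise InsufficientDataError("epoch shorter than 2 samples")
    starts = np.round(events.times * channel.fs).astype(int)
    usable = starts[(starts >= 0) & (starts + n_epoch <= len(channel.samples))]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} usable epochs (need >= 3)")
    epochs = np.stack([channel.samples[s:s + n_epoch] for s in usable])
    return ArterialPulsationSignal(
        samples=-epochs.mean(axis=0), fs=channel.fs,
        epoch_length=n_epoch / channel.fs, n_epochs_averaged=len(usable),
        median_rr=median_rr, channel_id=channel.channel_id)


def _cardiac_band_snr_db(s: ArterialPulsationSignal) -> float:
    """Power at the cardiac fundamental and 2nd harmonic vs the rest (dB)."""
    x = s.samples - s.samples.mean()
    n = len(x)
    if n < 8 or np.allclose(x, 0):
        return float("-inf")
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / s.fs)
    f0 = 1.0 / s.median_rr
    in_band = np.zeros(len(freqs), dtype=bool)
    for k in (1, 2, 3, 4):
        in_band |= np.abs(freqs - k * f0) <= 0.35 * f0
    p_sig = spec[in_band].sum()
    p_rest = spec[~in_band].sum()
    if p_rest <= 0:
        return float("inf")
    return float(10.0 * np.log10(p_sig / p_rest))


def _template_correlation(s: ArterialPulsationSignal) -> float:
    """Correlation of cycle 1 with the (possibly partial) cycle 2 overlap."""
    n_cycle = int(round(s.median_rr * s.fs))
    second = s.samples[n_cycle:]
    m = min(len(second), n_cycle)
    if m < 4:
        return float("nan")
    a, b = s.samples[:m], second[:m]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def quality_control(s: ArterialPulsationSignal,
                    snr_floor_db: float = SNR_FLOOR_DB_DEFAULT) -> QualityReport:
    """Automated stand-in for visual pulse-shape inspection.

    A channel passes iff, on its first cardiac cycle, (a) the global maximum
    lies strictly inside the cycle, (b) both cycle endpoints lie below the
    cycle mean (low diastolic shoulders with a systolic rise in between),
    and (c) the cardiac-band SNR is at or above the configured floor.
    """
    cycle = s.first_cycle()
    reasons = []
    imax = int(np.argmax(cycle))
    if imax == 0 or imax == len(cycle) - 1:
        reasons.append("no-pulse-shape")
    else:
        mean = cycle.mean()
        if not (cycle[0] < mean and cycle[-1] < mean):
            reasons.append("no-pulse-shape")
    snr = _cardiac_band_snr_db(s)
    if not (snr >= snr_floor_db):
        reasons.append("low-snr")
    return QualityReport(channel_id=s.channel_id, passed=not reasons,
                         reasons=reasons, snr_db=snr,
                         template_correlation=_template_correlation(s))


def preprocess_channel(channel: RawChannel, events: RPeakEvents,
                       band: tuple[float, float] = BAND_DEFAULT,
                       epoch_factor: float = EPOCH_FACTOR_DEFAULT,
                       ) -> ArterialPulsationSignal:
    """normalize -> band-pass -> epoch-average one channel."""
    return epoch_average(bandpass(normalize_channel(channel), *band),
                         events, epoch_factor=epoch_factor)
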