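"""In-memory containers for raw and derived pulsation signals.

The central object is :class:`ArterialPulsationSignal` — the epoch-averaged,
sign-flipped optical waveform *s*, time-locked to the ECG R peak — which every
downstream index (timing index, PReFx) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RawChannel:
    """One optical channel: intensity trace plus source–detector distance.

    Parameters
    ----------
    samples:
        Raw (or partially processed) intensity trace, arbitrary units.
    fs:
        Sampling rate in Hz.
    channel_id:
        Opaque channel token, e.g. ``"S3-D1"`` or ``"ch07"``.
    sd_distance:
        Source–detector separation in millimetres; governs cortical
        sensitivity (20–60 mm channels sample the cortex).
    """

    samples: np.ndarray
    fs: float
    channel_id: str
    sd_distance: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.sd_distance <= 0:
            raise ValueError("sd_distance must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "RawChannel":
        return RawChannel(np.asarray(samples, dtype=float), self.fs,
                          self.channel_id, self.sd_distance)


@dataclass
class RPeakEvents:
    """ECG R-peak event times in seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def median_rr(self) -> float:
        """Median inter-beat (R-R) interval in seconds."""
        if len(self.times) < 2:
            raise ValueError("need at least 2 events for an R-R interval")
        return float(np.median(np.diff(self.times)))


@dataclass
class ArterialPulsationSignal:
    """Epoch-averaged, sign-flipped arterial pulsation signal *s*.

    Sample 0 corresponds to an ECG R peak (``t0 = 0``); amplitudes are
    dimensionless after mean-normalisation. ``median_rr`` is the median
    R-R interval the epochs were cut with, used downstream for cardiac
    cycle segmentation.
    """

    samples: np.ndarray
    fs: float
    epoch_length: float
    n_epochs_averaged: int
    median_rr: float
    channel_id: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.n_epochs_averaged < 1:
            raise ValueError("n_epochs_averaged must be >= 1")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the R peak."""
        return self.t0 + np.arange(len(self.samples)) / self.fs

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def first_cycle(self) -> np.ndarray:
        """Samples of the first cardiac cycle (one median R-R interval)."""
        n = int(round(self.median_rr * self.fs))
        return self.samples[: min(n + 1, len(self.samples))]

    def with_samples(self, samples: np.ndarray) -> "ArterialPulsationSignal":
        return ArterialPulsationSignal(
            np.asarray(samples, dtype=float), self.fs, self.epoch_length,
            self.n_epochs_averaged, self.median_rr, self.channel_id, self.t0)


@dataclass
class QualityReport:
    """Outcome of the automated pulse-shape / SNR screen for one channel."""

    channel_id: str
    passed: bool
    reasons: list = field(default_factory=list)
    snr_db: float = float("nan")
    template_correlation: float = float("nan")

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")
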