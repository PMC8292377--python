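"""Comparator vascular indices: MRI pulsatility, TCD augmentation, CRF.

These are the established indices the NiRS-derived measures are validated
against. The pulsatility index PI = (F_max - F_min)/F_mean summarises flow
waveform excursion; the augmentation index AI = (V_refl - V_dia)/(V_sys -
V_dia) measures how much the reflected wave augments the velocity pulse;
CRF is a non-exercise linear regression estimate of cardiorespiratory
fitness from demographics, with eCRF dropping the sex term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingCovariateError, NirsPulseError
from .signals import RPeakEvents, RawChannel
from .preprocessing import epoch_average


@dataclass
class FlowExtrema:
    """Per-artery MRI flow extrema (e.g. ml/s) over the cardiac cycle."""

    f_max: float
    f_min: float
    f_mean: float
    side: str = "left"

    def __post_init__(self):
        if not (self.f_min <= self.f_mean <= self.f_max):
            raise ValueError("need f_min <= f_mean <= f_max")
        if self.f_mean <= 0:
            raise NirsPulseError("mean flow must be positive")


@dataclass
class VelocityFiducials:
    """Characteristic points on an averaged Doppler velocity waveform, cm/s."""

    v_sys: float
    v_dia: float
    v_refl: float
    side: str = "left"

    def __post_init__(self):
        if not (self.v_dia < self.v_refl <= self.v_sys):
            # v_refl == v_sys is the degenerate fully fused reflection
            raise ValueError("need v_dia < v_refl <= v_sys")


@dataclass
class SubjectCovariates:
    """Demographics feeding the non-exercise fitness model."""

    age: float
    sex: str                 # "M" | "F"
    bmi: float
    resting_hr: float
    activity_score: float

    def __post_init__(self):
        for name in ("age", "bmi", "resting_hr"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise MissingCovariateError(name)
        if self.sex not in ("M", "F"):
            raise MissingCovariateError("sex")
        if self.activity_score is None or not np.isfinite(self.activity_score):
            raise MissingCovariateError("activity_score")


def pi_mri(extrema: list[FlowExtrema] | FlowExtrema) -> float:
    """Subject pulsatility index: per-artery PI, averaged over sides."""
    if isinstance(extrema, FlowExtrema):
        extrema = [extrema]
    if not 1 <= len(extrema) <= 2:
        raise NirsPulseError("expected flow extrema for 1 or 2 arteries")
    pis = [(e.f_max - e.f_min) / e.f_mean for e in extrema]
    return float(np.mean(pis))


def ai_tcd(fiducials: list[VelocityFiducials] | VelocityFiducials) -> float:
    """Subject augmentation index, averaged over available arteries."""
    if isinstance(fiducials, VelocityFiducials):
        fiducials = [fiducials]
    ais = []
    for f in fiducials:
        denom = f.v_sys - f.v_dia
        if denom <= 0:
            raise NirsPulseError("degenerate waveform: v_sys == v_dia")
        ais.append((f.v_refl - f.v_dia) / denom)
    return float(np.mean(ais))


def average_velocity_waveform(channel: RawChannel,
                              diastolic_peaks: RPeakEvents,
                              epoch_factor: float = 1.0):
    """Diastolic-peak-locked averaging of a Doppler velocity trace.

    Mirrors the R-peak-locked averaging used for the optical channels but
    locks to diastolic peaks and preserves polarity (velocity is recorded
    with systole already positive, so no flip).
    """
    s = epoch_average(channel, diastolic_peaks, epoch_factor=epoch_factor)
    return s.with_samples(-s.samples)  # undo the optical sign flip


# Default non-exercise fitness coefficients (METs). Provisional values in
# the style of the published sex/age/BMI/resting-HR/activity regressions;
# replace with a study-specific set via configuration when available.
CRF_COEFFICIENTS_DEFAULT = {
    "intercept": 18.07,
    "sex_male": 2.77,
    "age": -0.10,
    "bmi": -0.17,
    "resting_hr": -0.03,
    "activity_score": 0.32,
}


def crf(c: SubjectCovariates,
        coefficients: dict | None = None) -> tuple[float, float]:
    """Non-exercise CRF estimate and its sex-free variant eCRF.

    crf = intercept + sex_male*[sex==M] + age*age + bmi*bmi
          + resting_hr*hr + activity_score*score;  ecrf drops the sex term.
    """
    co = dict(CRF_COEFFICIENTS_DEFAULT)
    if coefficients:
        co.update(coefficients)
    ecrf_value = (co["intercept"]
                  + co["age"] * c.age
                  + co["bmi"] * c.bmi
                  + co["resting_hr"] * c.resting_hr
                  + co["activity_score"] * c.activity_score)
    crf_value = ecrf_value + (co["sex_male"] if c.sex == "M" else 0.0)
    return float(crf_value), float(ecrf_value)
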