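"""Run configuration: every tunable threshold of the analysis pipeline.

Defaults are the values used throughout the package's documentation:
0.5-5.0 Hz band, 20-60 mm channel selection, 125 ms / 500 ms fiducial
thresholds, mean +/- 1.5 SD outlier fence, PReFx interval [-0.1, 0.4],
channel-count minima (>= 10 for TI, > 10 for PReFx), FDR alpha 0.05.
Configs serialize to flat YAML and embed a content hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .comparators import CRF_COEFFICIENTS_DEFAULT
from .errors import InvalidConfigError


@dataclass
class RunConfig:
    band_lo_hz: float = 0.5
    band_hi_hz: float = 5.0
    sd_min_mm: float = 20.0
    sd_max_mm: float = 60.0
    epoch_factor: float = 1.8
    smoothing: bool = True
    smoothing_window: int = 7
    smoothing_order: int = 3
    t_sys_min_ms: float = 125.0
    t_refl_max_ms: float = 500.0
    sd_fence: float = 1.5
    prefx_lo: float = -0.1
    prefx_hi: float = 0.4
    min_channels_ti: int = 10
    min_channels_prefx: int = 10       # strict: need count > this for PReFx
    snr_floor_db: float = 3.0
    alpha: float = 0.05
    seed: int = 0
    crf_coefficients: dict = field(
        default_factory=lambda: dict(CRF_COEFFICIENTS_DEFAULT))

    def validate(self, fs: float | None = None) -> "RunConfig":
        """Check internal consistency; ``fs`` also checks the Nyquist bound."""
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise InvalidConfigError("band: need 0 < lo < hi")
        if fs is not None and self.band_hi_hz >= fs / 2:
            raise InvalidConfigError(
                f"band_hi_hz={self.band_hi_hz} must be below Nyquist ({fs / 2})")
        if self.sd_min_mm >= self.sd_max_mm:
            raise InvalidConfigError("sd window: need min < max")
        if self.epoch_factor <= 1.0:
            raise InvalidConfigError("epoch_factor must exceed 1 cycle")
        if self.smoothing_window <= self.smoothing_order:
            raise InvalidConfigError("smoothing window must exceed order")
        if self.t_sys_min_ms < 0 or self.t_refl_max_ms <= self.t_sys_min_ms:
            raise InvalidConfigError("fiducial thresholds inconsistent")
        if self.prefx_lo >= self.prefx_hi:
            raise InvalidConfigError("PReFx interval empty")
        if not (0 < self.alpha < 1):
            raise InvalidConfigError("alpha must be in (0, 1)")
        if self.min_channels_ti < 1 or self.min_channels_prefx < 1:
            raise InvalidConfigError("channel minima must be >= 1")
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(
                f"unknown config fields: {sorted(unknown)}")
        return cls(**data).validate()

    @property
    def config_hash(self) -> str:
        """Short content hash embedded in outputs for provenance."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
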