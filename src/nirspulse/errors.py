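"""Exception hierarchy shared across the package.

Channel-level rejections raise :class:`ChannelExcluded` carrying a rule
identifier so exclusion cascades stay auditable; everything else is a
plain error.
"""


class NirsPulseError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(NirsPulseError):
    """A simulation spec violates its invariants."""


class InvalidConfigError(NirsPulseError):
    """A run configuration value is out of range or inconsistent."""


class DegenerateChannelError(NirsPulseError):
    """A raw channel cannot be processed (e.g. zero mean)."""


class InsufficientDataError(NirsPulseError):
    """Too little data for the requested operation."""


class DegenerateGeometryError(NirsPulseError):
    """PReFx rectangle has non-positive area."""


class MissingCovariateError(NirsPulseError):
    """A required subject covariate is absent."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing covariate: {field!r}")


class ChannelExcluded(NirsPulseError):
    """A channel failed a documented exclusion rule.

    Parameters
    ----------
    rule:
        Short rule identifier, e.g. ``"zc<4"`` or ``"bad-window"``.
    """

    def __init__(self, rule: str, message: str = ""):
        self.rule = rule
        super().__init__(message or f"channel excluded by rule {rule!r}")
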