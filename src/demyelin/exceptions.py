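"""Exception hierarchy.

All domain/validation failures derive from :class:`DemyelinError` so callers
can catch the package's errors with a single except clause; most also derive
from ``ValueError`` to behave sensibly in generic numeric code.
"""


class DemyelinError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(DemyelinError, ValueError):
    """A parameter is outside its physical/mathematical domain."""


class NegativeDemyelinationError(DomainError):
    """Treated thickness exceeds the baseline (gamma would be negative)."""


class ConfigError(DemyelinError, ValueError):
    """A model configuration file or mapping is invalid."""


class NumericalInstabilityError(DemyelinError, ArithmeticError):
    """The time stepper produced non-finite voltages."""


class PropagationFailureError(DemyelinError, RuntimeError):
    """The travelling wave never reached the distal measurement node."""


class DegenerateMeasurementError(DemyelinError, ValueError):
    """Velocity measurement is degenerate (equal crossing times)."""


class CalibrationError(DemyelinError, RuntimeError):
    """Baseline calibration could not reach the target velocity."""


class ExtrapolationError(DemyelinError, ValueError):
    """A velocity lies outside the tabulated NCV curve's range."""


class FormatError(DemyelinError, ValueError):
    """A recording file or sidecar does not match the expected schema."""


class NoPeakError(DemyelinError, ValueError):
    """A channel contains no usable peak after the artifact-blank window."""


class DegenerateLatencyError(DemyelinError, ValueError):
    """Peak-to-peak latency is zero or negative."""
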