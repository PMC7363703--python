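"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`RestDcxError` so callers can catch
pipeline failures without masking programming errors.
"""


class RestDcxError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(RestDcxError, ValueError):
    """A cohort or stage specification violates its documented domain."""


class StabilityError(RestDcxError, ValueError):
    """An autoregressive model is unstable (companion spectral radius >= 1)."""


class ShapeError(RestDcxError, ValueError):
    """Array dimensions do not match the operation's contract."""


class InvalidBandError(RestDcxError, ValueError):
    """Filter band edges fall outside (0, Nyquist)."""


class InsufficientDataError(RestDcxError, ValueError):
    """Not enough clean data to satisfy the request."""


class SchemaError(RestDcxError, ValueError):
    """A table does not conform to its documented schema."""


class GeometryError(RestDcxError, ValueError):
    """Sensor/source geometry violates the forward-model preconditions."""


class CoverageError(RestDcxError, ValueError):
    """A parcel has no sources mapped to it."""


class UndefinedMetricError(RestDcxError, ValueError):
    """A graph metric is undefined for the given node set."""


class UndefinedEffectError(RestDcxError, ValueError):
    """Effect size undefined (zero pooled spread with unequal means)."""


class ConfigError(RestDcxError, ValueError):
    """Pipeline configuration contains unknown keys or invalid values."""
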