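"""Exception hierarchy for the process model.

All model-level failures derive from :class:`WheyfracError` so callers can
distinguish domain errors from programming errors.
"""


class WheyfracError(Exception):
    """Base class for all domain errors raised by this package."""


class ValidationError(WheyfracError, ValueError):
    """An input violates a documented physical or structural invariant."""


class SchemaError(ValidationError):
    """A tabular input does not match the expected column schema."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class SolubilityRangeError(WheyfracError):
    """Pressure falls outside the span of the CO2 solubility table."""


class ExtrapolationError(WheyfracError):
    """A query lies outside the convex hull of the experimental grid."""


class NoMatchingConditionError(WheyfracError):
    """No experimental row matches the requested (T, C, P) within tolerance."""


class UnreachablePHError(WheyfracError):
    """The requested pH cannot be reached within the allowed pressure range."""


class UnsupportedConcentrationError(WheyfracError):
    """Centrifuge selection is undefined at this WPI concentration."""


class ClosureError(WheyfracError):
    """A mass-balance closure produced a physically impossible value."""
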