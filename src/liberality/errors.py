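"""Exception hierarchy shared across the package.

All domain errors derive from :class:`LiberalityError` so callers (and the
CLI) can catch one base class and map it to a nonzero exit status.
"""


class LiberalityError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(LiberalityError):
    """A file could not be parsed (empty file, malformed header, ...)."""


class ValidationError(LiberalityError):
    """Parsed data violates a domain invariant."""


class SchemaError(ValidationError):
    """A required column is missing from a tabular input."""


class EmptyLibraryError(ValidationError):
    """A sample has zero total counts; occupation rates are undefined."""


class InsufficientDataError(ValidationError):
    """Too few samples for the requested statistical operation."""


class ZeroVarianceError(ValidationError):
    """The regression covariate is constant; the slope is unidentifiable."""


class EntropyRangeError(ValidationError):
    """A target entropy lies outside the range attainable by tempering."""


class PerfectFitWarning(UserWarning):
    """Residual sum of squares is zero; the slope p-value is reported as 0."""
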