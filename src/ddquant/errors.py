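"""Exception hierarchy shared across the package.

All ddquant errors derive from :class:`DdquantError` so callers can catch
pipeline failures in one clause while still distinguishing specific modes.
"""


class DdquantError(Exception):
    """Base class for all ddquant errors."""


class InvalidInputError(DdquantError, ValueError):
    """An argument violates a documented precondition."""


class SaturatedPartitionError(InvalidInputError):
    """Every accepted droplet is positive: the Poisson rate is unbounded.

    Raised instead of returning ``inf`` so batch pipelines can flag the well
    rather than propagate non-finite values.
    """


class InsufficientDataError(DdquantError, ValueError):
    """Too few observations for the requested statistic (e.g. RSD of one value)."""


class ReferenceAbsentError(InvalidInputError):
    """No reference-species copies detected: the sample is not a
    reference-background mixture and the mass ratio is undefined."""


class UndefinedDeviationError(InvalidInputError):
    """Relative deviation against a zero expected value is undefined."""


class SingularFitError(DdquantError, ValueError):
    """Regression design is degenerate (all x identical)."""


class SchemaError(DdquantError, ValueError):
    """A tabular input file does not conform to the expected schema."""


class MissingCalibrationError(DdquantError):
    """Quantification requested without a transfer-coefficient configuration."""
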