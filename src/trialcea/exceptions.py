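"""Exception hierarchy for the trialcea pipeline.

All package errors derive from :class:`TrialCEAError` so callers can catch
pipeline failures with a single except clause while still distinguishing the
stage that failed.
"""


class TrialCEAError(Exception):
    """Base class for all trialcea errors."""


class ConfigurationError(TrialCEAError):
    """A config object violates its invariants (probabilities, arm sizes, ...)."""


class ValidationError(TrialCEAError):
    """An input table or argument is malformed."""


class PreconditionError(TrialCEAError):
    """A documented precondition of an operation does not hold."""


class TariffCoverageError(TrialCEAError):
    """A level profile is absent from the tariff table."""


class PricingError(TrialCEAError):
    """A resource-use category has no unit price."""


class IndexationError(TrialCEAError):
    """No price-index factor is available for a source year."""


class ImputationError(TrialCEAError):
    """The imputation model cannot be fit (e.g. a variable with no observed values)."""


class SingularityError(TrialCEAError):
    """The regression design matrix is rank deficient."""
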