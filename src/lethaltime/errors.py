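"""Exception hierarchy shared across the package."""


class LethaltimeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LethaltimeError):
    """A delimited-text input is missing required columns."""


class DataValidationError(LethaltimeError):
    """A record violates a domain invariant (counts, signs, monotonicity)."""


class DomainError(LethaltimeError):
    """An argument is outside the mathematical domain of an operation."""


class SingularDesignError(LethaltimeError):
    """A regression design matrix is rank deficient (e.g. one distinct level)."""


class SeparationError(LethaltimeError):
    """Quantal data are completely separated: the probit MLE does not exist.

    Raised instead of returning a drifting pseudo-fit; callers that only need
    an interval statement should fall back to reporting the level range.
    """


class ConvergenceError(LethaltimeError):
    """Iteratively reweighted least squares failed to converge."""
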