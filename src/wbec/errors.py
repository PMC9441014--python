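"""Exception hierarchy for wbec.

All errors derive from :class:`WbecError` so callers can catch the package's
failures with a single except clause; the subclasses mirror the failure modes
of the analysis stages (invalid parameters, unstable dynamics, degenerate
data, schema mismatches on disk).
"""


class WbecError(Exception):
    """Base class for all wbec errors."""


class InvalidParameterError(WbecError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(WbecError, ValueError):
    """An input object violates a precondition (empty list, single class...)."""


class StabilityError(WbecError):
    """A MOU model has a Jacobian eigenvalue with non-negative real part."""


class InsufficientDataError(WbecError):
    """A time series is too short for the requested operation."""


class EstimationError(WbecError):
    """A quantity could not be estimated from the data (e.g. the
    autocovariance is non-positive at every node for a lag needed by the
    time-constant fit)."""


class NumericalError(WbecError):
    """A linear-algebra step failed (singular solve, bad residual)."""


class DivergenceError(WbecError):
    """The Lyapunov optimization diverged.  The last stable iterate is
    attached as ``last_stable_model``."""

    def __init__(self, message, last_stable_model=None, iteration=None):
        super().__init__(message)
        self.last_stable_model = last_stable_model
        self.iteration = iteration


class StandardizationError(WbecError):
    """A feature vector has zero variance and cannot be z-scored."""


class UndefinedCorrelationError(WbecError):
    """A correlation is undefined because one side has zero variance."""


class SchemaError(WbecError):
    """A file on disk does not match the expected schema."""


class ParseError(WbecError):
    """A cell in a file could not be parsed as a number."""
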