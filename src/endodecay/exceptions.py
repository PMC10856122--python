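"""Exception hierarchy for endodecay.

Every error raised on purpose by this package derives from
:class:`EndodecayError`, so callers can catch the package's failures
without swallowing genuine bugs.
"""


class EndodecayError(Exception):
    """Base class for all endodecay errors."""


class ConfigError(EndodecayError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(EndodecayError, ValueError):
    """An argument outside the mathematical domain of an operation
    (negative time, non-decay rate constant, non-positive baseline, ...)."""


class InsufficientDataError(EndodecayError, ValueError):
    """Too few observations for the requested fit or test."""


class ConvergenceError(EndodecayError, RuntimeError):
    """The optimizer failed to produce an acceptable fit.

    Carries the best attempt (if any) on the ``best_attempt`` attribute.
    """

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class DegenerateDataError(EndodecayError, ValueError):
    """Data degenerate for the requested statistic (zero variance, zero
    residual sum of squares, empty contingency margin, ...)."""


class EmptyInputError(EndodecayError, ValueError):
    """A selection or series that must be non-empty is empty."""
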