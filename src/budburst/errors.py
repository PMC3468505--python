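"""Exception hierarchy shared across the package."""


class BudburstError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BudburstError, ValueError):
    """A configuration or parameter value violates its contract."""


class ParameterError(ValidationError):
    """A model parameter vector is out of bounds or mis-ordered."""


class RangeError(BudburstError, ValueError):
    """A requested day window falls outside the support of a series."""


class AlignmentError(BudburstError, ValueError):
    """Two daily series do not share the required day axis."""


class ParseError(BudburstError, ValueError):
    """A CSV/YAML input could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class IntegrityError(BudburstError, ValueError):
    """Duplicate or inconsistent records in an observation table."""


class DesignError(BudburstError, ValueError):
    """A synthetic experiment design cannot produce observable budburst."""


class InitializationError(BudburstError, RuntimeError):
    """The MCMC sampler could not find a starting point with finite likelihood."""


class PerfectFitError(BudburstError, ValueError):
    """Residual sum of squares is zero, so log-based criteria are undefined."""
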