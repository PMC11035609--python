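"""Exception hierarchy shared across the package."""


class WbcPgsError(Exception):
    """Base class for package errors."""


class ConfigError(WbcPgsError, ValueError):
    """A configuration value is outside its documented domain."""


class ValidationError(WbcPgsError, ValueError):
    """Record-level input validation failed; ``rows`` lists offenders."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = rows if rows is not None else []


class LookupFailure(WbcPgsError, KeyError):
    """A required variant or column is absent from its container."""


class InsufficientDataError(WbcPgsError, ValueError):
    """Too few observations to carry out the requested computation."""


class DegenerateInputError(WbcPgsError, ValueError):
    """Input is degenerate (e.g. zero variance) for the requested operation."""


class FitError(WbcPgsError, RuntimeError):
    """A model fit failed (separation, non-convergence, rank deficiency).

    ``diagnostics`` carries whatever the fitter could salvage.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
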