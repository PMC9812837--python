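"""Exception hierarchy for rangeshift.

All errors derive from :class:`RangeshiftError` so callers can catch the
package's failures with a single except clause; the CLI maps subclasses to
exit codes (config errors -> 2, data errors -> 3, convergence -> 4).
"""


class RangeshiftError(Exception):
    """Base class for all rangeshift errors."""


class InvalidConfigurationError(RangeshiftError, ValueError):
    """A parameter or configuration value is out of its valid domain."""


class InsufficientDataError(RangeshiftError, ValueError):
    """Too few observations to perform the requested operation."""


class DataFormatError(RangeshiftError, ValueError):
    """An input table violates the survey schema (columns, finiteness, 0/1)."""


class RankDeficiencyError(RangeshiftError, ValueError):
    """The design matrix is singular (e.g. one distinct year with a linear form)."""


class ConvergenceError(RangeshiftError, RuntimeError):
    """An iterative fit failed to converge."""


class BoundaryConvergenceError(ConvergenceError):
    """The breakpoint estimate was driven to the edge of its admissible range."""

    def __init__(self, side: str, psi: float):
        self.side = side
        self.psi = psi
        super().__init__(
            f"breakpoint driven to the {side} boundary of its admissible "
            f"range (psi = {psi:.4g}); the data do not support an interior "
            "breakpoint"
        )


class SmallSampleError(RangeshiftError, ValueError):
    """n <= k + 1, so the small-sample AIC correction is undefined."""


class IncomparableModelsError(RangeshiftError, ValueError):
    """Candidate models were not fitted to the same data."""


class TestUndefinedError(RangeshiftError, ValueError):
    """A test statistic is undefined (e.g. perfect fit leaves no residuals)."""
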