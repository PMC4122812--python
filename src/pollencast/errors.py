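"""Exception hierarchy.

All package errors derive from :class:`PollencastError` so callers (and the
CLI) can distinguish input/validation problems (exit code 1) from runtime
failures (exit code 2).
"""


class PollencastError(Exception):
    """Base class for all package errors."""


class ValidationError(PollencastError):
    """Invalid or inconsistent input data."""


class GapError(ValidationError):
    """A gap in a daily series too long to interpolate."""


class NoSeasonError(PollencastError):
    """Cumulative pollen sum never reached the season-start threshold."""

    def __init__(self, message: str, attained: float):
        super().__init__(message)
        #: total cumulative sum actually attained
        self.attained = attained


class IncompleteYearError(ValidationError):
    """A year has detected local minima but no observed season start."""


class SeparationError(PollencastError):
    """Perfect separation: logistic ML estimates diverge."""


class ConvergenceError(PollencastError):
    """Newton iterations did not converge."""
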