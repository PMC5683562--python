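"""Exception hierarchy shared across the package."""


class EwsError(Exception):
    """Base class for all package errors."""


class FormatError(EwsError):
    """Input file cannot be parsed into the expected tabular layout."""


class ValidationError(EwsError):
    """Input violates a data-model invariant (duplicate years, empty subset...)."""


class UndefinedStatisticError(EwsError):
    """A statistic has no defined value on this sample (e.g. zero variance)."""


class DegenerateFitError(EwsError):
    """A regression fit is degenerate (zero residual variance, collinearity)."""


class ConvergenceError(EwsError):
    """An iterative estimator failed to converge; carries diagnostics."""
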