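"""Exception hierarchy shared across the package.

Pipeline-facing errors carry an ``exit_code`` so the command-line layer can
map failure classes to distinct process exit statuses (schema = 2,
convergence = 3, alignment = 4).
"""


class LizardGrowthError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidIntervalError(LizardGrowthError, ValueError):
    """A growth interval violates its preconditions (e.g. non-positive days)."""


class SchemaError(LizardGrowthError, ValueError):
    """An input table is missing required columns or has malformed values."""

    exit_code = 2


class NonIdentifiableError(LizardGrowthError, ValueError):
    """The data cannot identify the model parameters (e.g. constant predictor)."""


class ConvergenceError(LizardGrowthError, RuntimeError):
    """An optimiser failed to converge where a converged fit is required."""

    exit_code = 3


class AlignmentError(LizardGrowthError, ValueError):
    """Environmental and growth series do not overlap in time."""

    exit_code = 4


class UnreachableSizeError(LizardGrowthError, ValueError):
    """A target length at or above the asymptote can never be reached."""
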