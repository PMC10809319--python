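"""Exception hierarchy for mcdock."""


class McdockError(Exception):
    """Base class for all package-specific errors."""


class InputError(McdockError, ValueError):
    """Invalid argument or precondition violation."""


class ShapeError(InputError):
    """Array shape does not match the system definition."""


class ConvergenceError(McdockError):
    """Iterative bias learning failed to converge.

    Carries a ``diagnostics`` dict describing the failure (e.g. the
    energy ranges visited by the two non-overlapping iterations).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IntegrationError(McdockError):
    """Sampling diverged (energy exceeded the blow-up threshold)."""


class DegenerateEnsembleError(McdockError):
    """Reweighting produced unusable weights.

    Carries the effective sample size observed at failure.
    """

    def __init__(self, message, effective_sample_size=None):
        super().__init__(message)
        self.effective_sample_size = effective_sample_size


class UndefinedStatisticError(McdockError):
    """A statistic was requested whose denominator is empty/zero."""


class ResolutionError(InputError):
    """A numerical resolution parameter is below the supported minimum."""


class PathGapError(McdockError):
    """A λ window along the binding path contains no snapshots."""

    def __init__(self, message, window=None):
        super().__init__(message)
        self.window = window


class ParseError(McdockError):
    """A file could not be parsed; the message names the offending line."""


class SpecError(InputError):
    """A synthetic-data specification is internally inconsistent."""
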