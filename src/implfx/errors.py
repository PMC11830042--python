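"""Exception hierarchy shared across the analytic modules."""


class ImplfxError(Exception):
    """Base class for all package errors."""


class ParameterError(ImplfxError, ValueError):
    """A simulation or model parameter violates its invariant."""


class DataError(ImplfxError, ValueError):
    """Input data violate a structural precondition (gaps, duplicates, range)."""


class StructuralError(DataError):
    """Dataset-level structural violation (empty panel, mismatched ranges)."""


class ConfigurationError(ImplfxError, ValueError):
    """Invalid or contradictory run configuration."""


class DegenerateFitError(ImplfxError, RuntimeError):
    """A model fit is degenerate (e.g. a segment with zero variance)."""


class InferenceError(ImplfxError, RuntimeError):
    """Resampling-based inference failed (too many bootstrap refit failures)."""


class ConvergenceError(ImplfxError, RuntimeError):
    """MCMC did not reach the configured convergence diagnostics."""

    def __init__(self, message: str, offenders: list | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class UndefinedResultError(ImplfxError, ZeroDivisionError):
    """A set-theoretic measure is undefined (empty denominator)."""
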