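"""Typed errors raised across the package.

Every malformed input raises one of these rather than being silently
coerced; the pipeline catches them per target/outcome pair so one bad
analysis never aborts a batch.
"""


class DtmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DtmrError):
    """A config file, column mapping or CLI argument is unusable."""


class SumStatsValidationError(DtmrError):
    """A summary-statistics row violates a field invariant.

    Carries the 1-based data row index when raised during file reading.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class RegionValidationError(DtmrError):
    """A region catalog entry violates an interval or enum invariant."""


class LDMatrixError(DtmrError):
    """An LD matrix is non-square, asymmetric or out of range."""


class EmptyRegionError(DtmrError):
    """No variants fall inside the requested target's regions (n = 0)."""


class AlleleMismatchError(DtmrError):
    """Exposure and outcome alleles are not the same unordered pair."""


class DegenerateInstrumentError(DtmrError):
    """An instrument has zero exposure effect (undefined Wald ratio)."""


class MethodNotApplicableError(DtmrError):
    """Too few instruments for the requested estimator."""


class ConvergenceError(DtmrError):
    """An iterative estimator failed to converge after multi-start."""
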