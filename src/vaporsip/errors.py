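"""Typed errors raised across the pipeline.

Every malformed input raises one of these; the pipeline never emits a silent
NaN for a validation failure.
"""


class VaporSipError(Exception):
    """Base class for all package errors."""


class SchemaError(VaporSipError):
    """A table is missing a required column or carries an unknown label."""


class RowError(VaporSipError):
    """A single row failed to parse; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(VaporSipError):
    """Run configuration violates an invariant (e.g. a_w outside (0, 1])."""


class DomainError(VaporSipError):
    """A value is outside the mathematical domain of an operation."""


class DegenerateFitError(VaporSipError):
    """A fit cannot be identified from the data supplied (e.g. one standard)."""


class FitError(VaporSipError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, initial_guess=None, residuals=None):
        self.initial_guess = initial_guess
        self.residuals = residuals
        super().__init__(message)


class DataError(VaporSipError):
    """Not enough observations for the requested operation."""


class MassBalanceError(VaporSipError):
    """Two-pool label accounting produced a physically impossible value."""


class QuantificationError(VaporSipError):
    """Internal-standard quantification is impossible for a sample."""


class DegenerateSampleError(VaporSipError):
    """A per-sample denominator (pool size) is zero."""


class UndefinedRatioError(VaporSipError):
    """A requested ratio has a zero denominator."""


class TruthError(VaporSipError):
    """Synthetic ground-truth parameters are unphysical."""
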