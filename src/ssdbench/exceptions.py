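"""Exception hierarchy for the ssdbench pipeline.

Exit-code mapping used by the CLI: ConfigError -> 1, DataError and
subclasses -> 2, NumericError and subclasses -> 3.
"""


class SSDBenchError(Exception):
    """Base class for all package errors."""


class ConfigError(SSDBenchError):
    """Invalid run configuration (bad key, type, range, or enum value)."""


class DataError(SSDBenchError):
    """Problems with input data."""


class SchemaError(DataError):
    """A mandatory column is missing or unresolvable."""


class RowValidationError(DataError):
    """A single row failed validation (non-positive value, bad unit...)."""


class DataInconsistencyError(DataError):
    """Contradictory records, e.g. one species under two taxonomic groups."""


class InsufficientDataError(DataError):
    """Too few observations for the requested operation."""


class NumericError(SSDBenchError):
    """Numerical failure (root not bracketed, undefined moments...)."""


class DomainError(NumericError, ValueError):
    """Argument outside the mathematical domain of the operation."""


class UnavailableEstimateError(NumericError):
    """An estimate was requested from a fit that did not converge."""


class EmptyEnsembleError(NumericError):
    """No converged fit survived; model averaging is impossible."""
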