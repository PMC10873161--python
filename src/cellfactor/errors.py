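"""Exception hierarchy and structured warnings."""


class CellFactorError(Exception):
    """Base class for all package errors."""


class ValidationError(CellFactorError):
    """Input values violate a documented contract (negative, non-finite, out of range)."""


class IdentifierError(CellFactorError):
    """Duplicate, unknown or misaligned gene/cell identifiers."""


class ShapeError(CellFactorError):
    """Matrix dimensions do not conform."""


class CoverageError(CellFactorError):
    """A cell of the expression matrix has no label."""


class ParameterError(CellFactorError):
    """Infeasible or out-of-range user parameter."""


class DegenerateOperatorError(CellFactorError):
    """The linear operator R*Sigma vanishes; no communication is inferable."""


class AggregationError(CellFactorError):
    """A cell type has no member cells during aggregation."""


class ComparisonError(CellFactorError):
    """Two type-level networks cannot be compared (label sets differ)."""


class DegenerateTruthError(CellFactorError):
    """A ground-truth table has only one class (all positive or all negative)."""


class ConfigError(CellFactorError):
    """Pipeline configuration is invalid."""


class RankDeficiencyWarning(UserWarning):
    """R*Sigma has column rank below the number of cells; part of W is undetermined."""


class AlignmentWarning(UserWarning):
    """Identifiers were dropped or zero-filled while aligning two artifacts."""
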