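"""Exception hierarchy for qsarval."""


class QsarValError(Exception):
    """Base class for all qsarval errors."""


class FormatError(QsarValError):
    """Structurally invalid input (duplicate identifiers, bad header, ...)."""


class ParseError(QsarValError):
    """A cell could not be parsed; message reports row and column."""


class InsufficientDataError(QsarValError):
    """Too few compounds for the requested computation."""


class SingularDesignError(QsarValError):
    """Rank-deficient design matrix; message names the dependent columns."""


class ParameterError(QsarValError):
    """Invalid parameter value (fractions, counts, thresholds)."""


class SchemaError(QsarValError):
    """A required column or descriptor is missing from the input."""


class UndefinedStatisticError(QsarValError):
    """A statistic's denominator degenerates (constant vector, zero norm)."""


class SubsetCapError(QsarValError):
    """The all-subset enumeration would exceed the configured cap."""
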