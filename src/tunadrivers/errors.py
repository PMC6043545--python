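"""Exception hierarchy shared across the pipeline stages."""


class TunaDriversError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TunaDriversError):
    """A configuration value is invalid or internally inconsistent."""


class ValidationError(TunaDriversError):
    """An input table or value violates a documented contract."""


class UnmappedUnitError(TunaDriversError):
    """No conversion rule covers an effort record's (org, gear, subtype, unit)."""


class AmbiguousRuleError(ConfigurationError):
    """More than one conversion rule matches the same record key."""


class UndefinedIndexError(TunaDriversError):
    """A diversity index is undefined (all-zero or empty effort vector)."""


class DeflatorGapError(TunaDriversError):
    """The deflator index does not cover every year of a nominal series."""


class SingularMatrixError(TunaDriversError):
    """X'X (or X'X + lambda*I) is singular or numerically ill-conditioned."""


class EmptyTableError(TunaDriversError):
    """A join or filter produced zero rows."""
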