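"""Typed exceptions raised across the pipeline.

Every validation or construction failure raises one of these, so callers can
distinguish malformed inputs (SchemaError and friends) from degenerate but
well-formed inputs (DegenerateDistanceError, DegenerateNullError).
"""


class UtilidivError(Exception):
    """Base class for all package errors."""


class SchemaError(UtilidivError):
    """A table is structurally wrong: missing/duplicate columns or ids."""


class ValidationError(UtilidivError, ValueError):
    """A cell value violates its declared domain (names row and column)."""


class ReferentialIntegrityError(UtilidivError):
    """A record refers to an entity absent from its companion table."""


class DegenerateDistanceError(UtilidivError):
    """All properties are constant across the pool; Gower distance undefined."""


class NonMonotoneLinkageError(UtilidivError):
    """Merge heights decreased; edge lengths cannot be defined."""


class UndefinedCorrelationError(UtilidivError):
    """Too few species (or zero variance) for a cophenetic correlation."""


class MembershipError(UtilidivError):
    """A community member is not a leaf of the dendrogram."""


class DegenerateNullError(UtilidivError):
    """Expected FD is non-positive; the Index of Variance is undefined."""


class CollinearityError(UtilidivError):
    """Rank-deficient design matrix in a linear model fit."""


class InsufficientDataError(UtilidivError):
    """Fewer observations than parameters to estimate."""


class ConfigError(UtilidivError):
    """A configuration object is internally inconsistent."""
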