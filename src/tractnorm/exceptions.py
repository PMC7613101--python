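"""Exception hierarchy.

All data-dependent failures derive from :class:`TractnormError` so the CLI
can map them to a single exit code distinct from usage errors.
"""


class TractnormError(Exception):
    """Base class for all package errors."""


class FormatError(TractnormError, ValueError):
    """A column name or file does not follow the expected convention."""


class ConsistencyError(TractnormError, ValueError):
    """Sheets/metrics disagree on subjects or feature keys."""


class LookupError_(TractnormError, KeyError):
    """Requested metric/subject/column not present."""


class DegenerateFeatureError(TractnormError, ValueError):
    """A feature is constant (zero variance / zero range) on the training set."""


class SingularCovariateError(TractnormError, ValueError):
    """Rank-deficient covariate design matrix."""

class ParameterError(TractnormError, ValueError):
    """Invalid user-supplied parameter value."""


class DimensionError(TractnormError, ValueError):
    """Feature count or key mismatch between model and data."""


class DataError(TractnormError, ValueError):
    """Non-finite or otherwise invalid values in a data matrix."""


class CohortSizeError(TractnormError, ValueError):
    """Too few subjects to satisfy the requested split or protocol."""


class InsufficientDataError(TractnormError, ValueError):
    """Too few observations for the requested statistic."""


class AlignmentError(TractnormError, ValueError):
    """Feature keys of two objects cannot be aligned."""
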