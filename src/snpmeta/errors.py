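"""Exception hierarchy for snpmeta.

All errors raised by the library derive from :class:`SnpMetaError` so callers
can catch one base class at pipeline boundaries.
"""


class SnpMetaError(Exception):
    """Base class for all snpmeta errors."""


class SchemaError(SnpMetaError):
    """An input table is missing a required column or has a bad header."""


class RowParseError(SnpMetaError):
    """A data row could not be parsed; message names the offending row."""


class DuplicateStudyError(SnpMetaError):
    """Two records share the same study_id."""


class FixtureLookupError(SnpMetaError, KeyError):
    """Unknown bundled fixture name; message lists valid names."""


class UndefinedInputError(SnpMetaError):
    """An operation was called on degenerate input (e.g. empty genotype arm)."""


class EstimateUndefinedError(SnpMetaError):
    """A 2x2 table admits no odds-ratio estimate (variant class empty in both arms)."""


class InsufficientStudiesError(SnpMetaError):
    """Fewer studies than the operation's minimum (bias tests need k >= 3, etc.)."""


class PoolingError(SnpMetaError):
    """Pooling is impossible (no usable tables after filtering)."""


class PipelineError(SnpMetaError):
    """End-to-end pipeline failure; message names the failing stage."""
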