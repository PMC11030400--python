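"""Exception hierarchy shared across the toolkit."""


class QcSentinelError(Exception):
    """Base class for all qcsentinel errors."""


class SchemaError(QcSentinelError):
    """A required column or field is missing from an input file."""


class ValidationError(QcSentinelError):
    """Input values violate a table invariant (negative area, duplicate key, ...)."""


class InsufficientDataError(QcSentinelError):
    """Too few points to compute the requested statistic."""


class ConfigurationError(QcSentinelError):
    """Invalid or contradictory configuration."""


class UndefinedScoreError(QcSentinelError):
    """A score is mathematically undefined for this input (distinct from a low score)."""
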