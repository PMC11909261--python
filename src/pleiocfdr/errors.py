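"""Exception hierarchy shared across the package."""


class PleioCfdrError(Exception):
    """Base class for all package errors."""


class FormatError(PleioCfdrError):
    """A file does not conform to the expected format (e.g. missing column)."""


class RecordError(PleioCfdrError):
    """A single record is malformed; the message carries the line number."""


class ConsistencyError(PleioCfdrError):
    """Inputs disagree on facts that must match (e.g. variant positions)."""


class ConfigError(PleioCfdrError):
    """A configuration value is out of its admissible range."""


class DomainError(PleioCfdrError):
    """A numeric input lies outside its mathematical domain."""


class UndefinedEnrichmentError(PleioCfdrError):
    """A fold-enrichment denominator is empty; the ratio is undefined."""


class InsufficientDataError(PleioCfdrError):
    """Too few observations to compute the requested statistic."""


class DegenerateDistributionError(PleioCfdrError):
    """A reference distribution has zero spread."""


class ConvergenceError(PleioCfdrError):
    """An iterative fit failed to converge; the message reports the last delta."""


class InstabilityError(PleioCfdrError):
    """A resampling procedure produced too many undefined replicates."""


class ModelError(PleioCfdrError):
    """Model construction failed (e.g. empty LD-pruned set)."""


class StageError(PleioCfdrError):
    """A pipeline stage failed; the message names the stage."""
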