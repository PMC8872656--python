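"""Exception hierarchy for the arraypulse pipeline."""


class ArrayPulseError(Exception):
    """Base class for all arraypulse errors."""


class FormatError(ArrayPulseError):
    """A recording or feature file does not match the expected layout."""


class IngestError(ArrayPulseError):
    """A file parsed but its contents are unusable (missing values, bad time base)."""


class ConfigError(ArrayPulseError, ValueError):
    """A configuration value violates an invariant."""


class FilterDesignError(ArrayPulseError):
    """Band-pass design failed or produced an unstable filter."""


class RecordTooShortError(ArrayPulseError):
    """Recording shorter than the filter settling requirement."""


class InsufficientDataError(ArrayPulseError):
    """Fewer beats (or samples) than an operation needs."""


class DegenerateBeatError(ArrayPulseError):
    """A beat with no rise above its onset level; fiducials undefined."""


class DegenerateVarianceError(ArrayPulseError):
    """Zero-variance samples with unequal means; the t statistic is undefined."""


class PipelineError(ArrayPulseError):
    """End-to-end analysis could not proceed (e.g. no segmentable channel)."""
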