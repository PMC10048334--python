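"""Exception hierarchy for triomut."""


class TriomutError(Exception):
    """Base class for all triomut errors."""


class InvalidConfigError(TriomutError, ValueError):
    """A configuration value violates its documented constraints."""


class MalformedInputError(TriomutError, ValueError):
    """An input table or record does not satisfy the expected layout."""


class MalformedRecordError(MalformedInputError):
    """A single site record is missing a required sample or field."""


class UndefinedRateError(TriomutError, ZeroDivisionError):
    """A rate was requested with a zero denominator."""


class UndefinedTestError(TriomutError, ValueError):
    """A statistical test was requested on degenerate input."""


class InsufficientReplicatesError(TriomutError, ValueError):
    """Too few bootstrap replicates for the percentile rule to be meaningful."""


class UndefinedCorrectionError(TriomutError, ZeroDivisionError):
    """Rate correction is undefined (false-negative rate of 1)."""


class ConsistencyError(TriomutError, ValueError):
    """Cross-input consistency check failed (e.g. reference base mismatch)."""
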