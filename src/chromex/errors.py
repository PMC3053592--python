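"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`ChromexError`
so callers can catch the whole family at the CLI boundary.
"""


class ChromexError(Exception):
    """Base class for all chromex errors."""


class ParseError(ChromexError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ChromexError):
    """Parsed data violates a structural invariant."""


class ConfigError(ChromexError):
    """A configuration value is out of its legal range."""


class UsageError(ChromexError):
    """An operation was called with arguments outside its contract."""


class InsufficientDataError(ChromexError):
    """Not enough data to compute a statistic (e.g. < 3 nonempty groups)."""


class UndefinedSimilarityError(ChromexError):
    """Similarity is 0/0 for this input (e.g. TCS with two empty TF sets)."""
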