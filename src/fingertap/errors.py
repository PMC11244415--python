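"""Typed exception hierarchy.

Every error raised by this package derives from :class:`FingertapError`,
so callers can catch the whole family with one clause while tests can
assert the precise failure mode.
"""


class FingertapError(Exception):
    """Base class for all errors raised by fingertap."""


class FormatError(FingertapError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class DataError(FingertapError):
    """The data content is invalid (non-monotone time, irregular sampling...)."""


class ConfigError(FingertapError):
    """A configuration or parameter object violates its invariants."""


class DomainError(FingertapError, ValueError):
    """A scalar argument is outside the mathematical domain of an operation."""


class InsufficientEventsError(DataError):
    """Too few tap events (or pairs) for the requested metric."""


class InsufficientDataError(DataError):
    """Too few cohort entries (repeats, participants) for the statistic."""


class DegenerateSignalError(DataError):
    """The signal carries no usable information (constant trace, zero variance)."""
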