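"""Exception hierarchy for dyadsync.

All package errors derive from :class:`DyadsyncError` so callers can catch
one base class; the leaf types distinguish bad user input from degenerate
data conditions.
"""


class DyadsyncError(Exception):
    """Base class for all dyadsync errors."""


class InputError(DyadsyncError):
    """A file or path could not be read."""


class FormatError(DyadsyncError):
    """Input was readable but malformed (ragged columns, mismatched frames)."""


class ConfigurationError(DyadsyncError):
    """Required configuration (e.g. frame rate) is missing or inconsistent."""


class ValidationError(DyadsyncError):
    """Values violate a domain constraint (e.g. negative energy)."""


class DomainError(DyadsyncError, ValueError):
    """Arguments outside the mathematical domain of an operation."""


class DegenerateInputError(DyadsyncError):
    """Input is formally valid but the quantity is undefined on it
    (constant series, all-zero correlation weights)."""


class UndefinedRatioError(DyadsyncError):
    """A ratio of bout durations is requested but one side has no bouts."""
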