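"""Exception hierarchy shared across the toolkit.

Every error raised by paa derives from :class:`PaaError`, so callers can
catch toolkit failures without masking programming errors.
"""


class PaaError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PaaError):
    """A file does not have the expected overall structure (e.g. missing header)."""


class ParseError(PaaError):
    """A cell or field could not be interpreted; the message names the location."""


class ValidationError(PaaError):
    """Structurally parseable input that violates a data invariant."""


class NotFoundError(PaaError, KeyError):
    """A queried entity is absent; the message may list near-miss suggestions."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class DegenerateInputError(PaaError):
    """Input that makes the requested statistic undefined (e.g. all-zero sample)."""


class InsufficientDataError(PaaError):
    """Too few usable observations for the requested fit."""
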