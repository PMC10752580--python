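"""Exception hierarchy.

All library errors derive from :class:`EntrainError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class EntrainError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EntrainError):
    """A file on disk does not match its expected layout."""


class ValidationError(EntrainError):
    """An in-memory object violates a structural invariant."""


class MissingColumnError(ValidationError):
    """A required metadata column is absent; treated as a configuration error."""
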