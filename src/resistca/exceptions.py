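"""Exception types shared across the package."""


class ResistCAError(Exception):
    """Base class for package errors."""


class OutOfDomainError(ResistCAError, ValueError):
    """A point or index falls outside the spatial grid."""


class FormatError(ResistCAError, ValueError):
    """An input file does not match the expected layout."""


class SchemaError(ResistCAError, ValueError):
    """A rule-set document violates the rule schema."""
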