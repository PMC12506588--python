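"""Exception hierarchy.

``UserInputError`` subclasses map to CLI exit code 1, anything else to 2.
"""


class EditasError(Exception):
    """Base class for all package errors."""


class UserInputError(EditasError):
    """Invalid user-supplied input (bad file, bad value, bad config)."""


class ParseError(UserInputError):
    """A file could not be parsed in its declared format."""


class SchemaError(UserInputError):
    """A table is missing required columns or has malformed ones."""


class ValidationError(UserInputError):
    """Parsed data violates a domain invariant (e.g. edited > coverage)."""
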