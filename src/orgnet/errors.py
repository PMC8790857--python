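"""Exception hierarchy for orgnet."""


class OrgnetError(Exception):
    """Base class for all orgnet errors."""


class SchemaError(OrgnetError):
    """An input table is missing required columns or is otherwise malformed."""


class ValidationError(OrgnetError):
    """A value violates a domain invariant (duplicate id, unknown category, ...)."""


class DLParseError(OrgnetError):
    """A UCINET DL file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AlignmentError(OrgnetError):
    """Layer networks do not share an identical ordered node set."""


class UndefinedMeasureError(OrgnetError):
    """A network measure is undefined for this network size."""
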