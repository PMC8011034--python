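"""Exceptions raised by the package."""


class GeneContextError(Exception):
    """Base class for all package errors."""


class ParseError(GeneContextError):
    """A file could not be parsed. Carries the path and, where known, the line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(GeneContextError):
    """Input data violates an invariant of the data model."""
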