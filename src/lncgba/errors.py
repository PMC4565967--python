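"""Exception hierarchy shared across the package."""


class LncgbaError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LncgbaError):
    """A text input file violates its expected dialect.

    Carries the 1-based line number when it is known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(LncgbaError):
    """An in-memory object or argument violates a contract."""
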