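"""Exception hierarchy for tham."""


class ThamError(Exception):
    """Base class for all tham errors."""


class InvalidParameterError(ThamError, ValueError):
    """A parameter is outside its documented domain."""


class BankError(ThamError):
    """Databank construction, validation or transfer failure."""


class ParseError(ThamError):
    """A text file (CIF, bank, tsc) could not be parsed."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += str(path)
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line
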