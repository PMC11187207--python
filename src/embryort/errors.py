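"""Exception hierarchy shared by all stages."""


class EmbryoRTError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EmbryoRTError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(EmbryoRTError, ValueError):
    """A text input file could not be parsed; carries the line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class InsufficientDataError(EmbryoRTError, ValueError):
    """Too few usable observations to compute the quantity."""


class DegenerateInputError(EmbryoRTError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero cell)."""


class SamplingFailureError(EmbryoRTError, RuntimeError):
    """Random-region sampling could not satisfy the length constraints."""


class UndefinedStatisticError(EmbryoRTError, ValueError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""
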