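"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError/ParseError -> 2,
ConvergenceError -> 3.
"""


class CbmScreenError(Exception):
    """Base class for all package errors."""


class ParseError(CbmScreenError):
    """An input file could not be parsed (names the record or line)."""


class ValidationError(CbmScreenError):
    """Input data violates a documented invariant."""


class ConvergenceError(CbmScreenError):
    """A nonlinear fit failed to converge or hit a degenerate optimum."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
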