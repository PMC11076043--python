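"""Exception hierarchy shared across the package."""


class SmtirfError(Exception):
    """Base class for all package errors."""


class ParameterError(SmtirfError, ValueError):
    """A configuration or argument value is outside its valid domain."""


class InputError(SmtirfError, ValueError):
    """Input data violates a precondition (empty, unfiltered, mismatched)."""


class FitError(SmtirfError, RuntimeError):
    """A nonlinear fit failed to converge or the data are degenerate.

    Carries optional diagnostics from the attempted starts.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
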