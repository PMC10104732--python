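"""Exception types shared across the toolkit."""


class CTFFRError(Exception):
    """Base class for all ctffr errors."""


class ValidationError(CTFFRError, ValueError):
    """An input violates a documented precondition or invariant."""


class ConvergenceError(CTFFRError, RuntimeError):
    """An iterative solve failed to meet its tolerance.

    Carries a ``diagnostics`` dict (bracket, residuals, iteration count)
    to make boundary-condition problems debuggable.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
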