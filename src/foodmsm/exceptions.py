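"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data or parameters violate a documented contract."""


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged fit but none is available."""
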