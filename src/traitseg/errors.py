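"""Exception types shared across the pipeline."""


class TraitsegError(Exception):
    """Base class for all package errors."""


class ValidationError(TraitsegError, ValueError):
    """Raised when an input violates a documented contract."""


class EstimationError(TraitsegError, RuntimeError):
    """Raised when a model fit cannot be carried out (singular design,
    all-zero response, null-model non-convergence)."""
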