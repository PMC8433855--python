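"""Exception hierarchy shared across the package."""


class RespredictError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(RespredictError):
    """A trace file violates the file dialect (headers, columns, cells)."""


class TraceValidationError(RespredictError):
    """Trace content violates a data-model invariant (non-finite, lengths...)."""


class ConfigurationError(RespredictError):
    """An invalid configuration value or combination."""


class TrainingError(RespredictError):
    """Optimization failed (non-finite cost)."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class DegenerateTestError(RespredictError):
    """A statistic is undefined on this input (e.g. all paired differences zero)."""
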