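"""Exception hierarchy shared across the package."""


class RespnetError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RespnetError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(RespnetError, ValueError):
    """An on-disk artifact does not conform to the expected dialect."""


class DivergenceError(RespnetError, RuntimeError):
    """The integrator produced a non-finite state."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state at integration step {step}")


class IntegrationStepError(RespnetError, ValueError):
    """The requested time step is too coarse for stable integration."""


class CalibrationError(RespnetError, RuntimeError):
    """A calibration search failed to bracket its target."""


class EmptyResultError(RespnetError, RuntimeError):
    """A selection operation found nothing to select from."""
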