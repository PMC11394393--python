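"""Exception types raised by hemoinfer."""


class HemoinferError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HemoinferError, ValueError):
    """A physical input (rate, noise level, parameter) is out of its domain."""


class DegenerateVolumeError(HemoinferError, ValueError):
    """Blood volume or hematocrit reached a value where the model is undefined."""


class SimulationDomainError(HemoinferError, RuntimeError):
    """The simulated state left the physiological domain before any stop rule."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class ObservabilityError(HemoinferError, ValueError):
    """The (A, C) pair is not observable; no observer gain exists."""


class DivergenceError(HemoinferError, RuntimeError):
    """Filter covariance blew up."""


class ConfigurationError(HemoinferError, ValueError):
    """A configuration block is inconsistent or infeasible."""


class EmptyCohortError(HemoinferError, ValueError):
    """No scored runs are available to compute a metric."""
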