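"""Package-wide exception types."""


class ApemuError(Exception):
    """Base class for all package errors."""


class ValidationError(ApemuError, ValueError):
    """Invalid user input (out-of-range parameter, malformed trace, ...)."""


class SimulationError(ApemuError, RuntimeError):
    """Numerical integration failure (non-finite state / voltage escape).

    Attributes
    ----------
    t_fail : float
        Simulation time in ms at which the state became invalid.
    """

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


class NoActionPotentialError(ApemuError, RuntimeError):
    """Trace contains no stimulus-evoked upstroke."""


class MissingAPDError(ApemuError, RuntimeError):
    """Repolarization level required for an APD was never reached."""


class CalibrationFailureError(ApemuError, RuntimeError):
    """Population calibration acceptance rate collapsed."""
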