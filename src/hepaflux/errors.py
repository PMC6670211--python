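"""Exception hierarchy for the hepaflux model."""


class HepafluxError(Exception):
    """Base class for all hepaflux errors."""


class InvalidInput(HepafluxError, ValueError):
    """An argument violates a precondition (negative concentration, unknown
    liver condition, zero protein fraction, ...)."""


class OutOfRange(InvalidInput):
    """A dietary protein intake outside the anchored range was passed where
    interpolation between printed anchors is required; extrapolation is
    refused."""


class ConfigError(HepafluxError, ValueError):
    """A scenario configuration file failed schema validation."""


class IntegrationError(HepafluxError, RuntimeError):
    """The ODE solver failed inside one zonation phase.

    Attributes
    ----------
    phase_index : int
        Zero-based index of the failing phase segment.
    """

    def __init__(self, message: str, phase_index: int | None = None):
        super().__init__(message)
        self.phase_index = phase_index


class InsufficientData(HepafluxError, ValueError):
    """A trajectory is too short for the requested analysis (e.g. steady-state
    detection needs at least three full acinus cycles)."""
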