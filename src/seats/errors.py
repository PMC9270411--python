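"""Exception hierarchy for the SEATS toolkit."""


class SeatsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SeatsError, ValueError):
    """A rate constant or derived quantity violates the model's assumptions."""


class SingularParametersError(ParameterError):
    """A closed-form expression is degenerate at the supplied parameters."""


class InvalidStateError(SeatsError, ValueError):
    """A state vector is non-finite, negative, or off the population simplex."""


class IntegrationError(SeatsError, RuntimeError):
    """The ODE solver failed before reaching the requested final time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time
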