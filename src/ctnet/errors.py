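"""Exception types raised by the simulation, spectral and statistical stages."""


class CtnetError(Exception):
    """Base class for all package-specific errors."""


class SimulationInstabilityError(CtnetError):
    """A state variable crossed the divergence guard during integration.

    Attributes
    ----------
    step : int
        Integration step at which the guard tripped.
    region : int
        Index of the offending region.
    """

    def __init__(self, step: int, region: int, message: str | None = None):
        self.step = step
        self.region = region
        super().__init__(
            message
            or f"state diverged at integration step {step} in region {region}"
        )


class LinearInstabilityError(CtnetError):
    """The linearized unit has a pole in the growth half-plane."""


class SteadyStateError(CtnetError):
    """Fixed-point search did not converge within the iteration budget."""


class DegenerateSignalError(CtnetError):
    """A region's series is (near-)constant, so its analytic phase is undefined."""


class SingularFitError(CtnetError):
    """Mixed-model fit is singular or failed to converge.

    The message names the variance component responsible where identifiable.
    """


class SchemaError(CtnetError):
    """An input table violates the documented column schema."""
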