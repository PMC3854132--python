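"""Exception types shared across the package."""


class BadnetError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(BadnetError, ValueError):
    """A kinetic or apoptosis parameter is outside its mathematical domain."""


class ContractViolationError(BadnetError, ValueError):
    """An input violates a documented structural contract (shape, sign, name)."""


class ConfigurationError(BadnetError, ValueError):
    """A treatment, readout or config entry cannot be mapped onto the model."""


class IntegrationFailureError(BadnetError, RuntimeError):
    """The ODE integrator produced NaN/blow-up or a non-trivial negative state.

    Carries ``time``, the first offending simulation time (hours).
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class UnreachableEffectError(BadnetError, ValueError):
    """A requested effect level exceeds the plateau of a dose-response curve.

    Distinct from numerical failure: the curve was evaluated successfully but
    saturates below the requested apoptosis percentage.
    """
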