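"""Exception hierarchy for the simulator."""


class OpioidLTPError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OpioidLTPError, ValueError):
    """A parameter value violates its documented invariant."""


class InputDomainError(OpioidLTPError, ValueError):
    """An operation was called outside its input domain (e.g. negative time)."""


class ModelConsistencyError(OpioidLTPError, RuntimeError):
    """A derived quantity violates a model invariant (e.g. negative conductance)."""


class IntegrationError(OpioidLTPError, RuntimeError):
    """The integrator produced a non-finite state.

    Carries the first offending state variable and the simulation time at
    which it occurred.
    """

    def __init__(self, variable: str, t_ms: float):
        self.variable = variable
        self.t_ms = t_ms
        super().__init__(
            f"non-finite value in state variable {variable!r} at t = {t_ms:.3f} ms"
        )


class StateCorruptionError(OpioidLTPError, RuntimeError):
    """State invariants were breached more often than the engine tolerates."""


class DegenerateNormalizationError(OpioidLTPError, ValueError):
    """Min-max normalization was requested for an all-equal input."""
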