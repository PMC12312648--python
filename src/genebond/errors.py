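"""Exception types shared across the package."""


class GenebondError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GenebondError):
    """A model or parameter record is structurally invalid."""


class UnsupportedLawError(GenebondError):
    """An operation only defined for mass-action reactions met another law."""


class CompositionError(GenebondError):
    """Modules could not be merged (port collision or inconsistent constants)."""


class StateError(GenebondError):
    """A state vector produced non-finite potentials or fluxes."""


class SolverError(GenebondError):
    """The ODE solver failed; carries the last valid state."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class NoSteadyStateError(GenebondError):
    """The trajectory does not converge to a steady state (e.g. limit cycle)."""


class NoLimitCycleError(GenebondError):
    """No converged oscillation could be extracted from the trajectory."""
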