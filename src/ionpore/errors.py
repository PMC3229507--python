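"""Exception and warning types shared across the package."""


class IonporeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(IonporeError, ValueError):
    """A physical parameter is out of its valid domain."""


class ConfigurationError(IonporeError, ValueError):
    """An analysis was configured inconsistently (regions, grids, ratios)."""


class EmptyInputError(IonporeError, ValueError):
    """An operation received an empty trajectory / event list."""


class TrajectoryFormatError(IonporeError, ValueError):
    """A trajectory file violates the format or a Trajectory invariant."""


class PackingError(IonporeError, RuntimeError):
    """Initial particle placement could not satisfy the overlap constraints."""


class ConvergenceError(IonporeError, RuntimeError):
    """An iterative solver did not reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class StabilityWarning(UserWarning):
    """The BD time step is large relative to the contact radius."""


class SkipWarning(UserWarning):
    """A frame spacing allows particles to skip the pore slab in one step."""
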