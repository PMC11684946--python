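"""Exception hierarchy shared across the workbench."""


class AlveoflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(AlveoflowError):
    """Geometric parameters are inconsistent (e.g. mouth wider than alveolus)."""


class NoSolutionError(AlveoflowError):
    """A root solve has no solution in the attainable range."""


class PlacementError(AlveoflowError):
    """Random placement of pores/ports failed after bounded retries."""


class MeshingError(AlveoflowError):
    """Surface triangulation failed or input was degenerate."""


class SingularSystemError(AlveoflowError):
    """Linear system has no Dirichlet anchor (no outlet port/node)."""


class ConvergenceError(AlveoflowError):
    """Iterative solve exceeded its iteration budget."""

    def __init__(self, message: str, residual: float | None = None,
                 history: list | None = None):
        super().__init__(message)
        self.residual = residual
        self.history = history or []


class EmptyBandError(AlveoflowError):
    """A position-speed measurement band contains no mesh elements."""


class ResolutionError(AlveoflowError):
    """Numerical resolution too coarse for the requested computation."""


class InsufficientDataError(AlveoflowError):
    """Too few distinct points for a regression."""


class OutOfRangeError(AlveoflowError):
    """Inverted quantity falls outside the physically meaningful range."""


class InconsistentObservationError(AlveoflowError):
    """No connectivity model set agrees with the observed value pair."""
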