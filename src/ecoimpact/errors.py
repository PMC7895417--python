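"""Exception hierarchy for ecoimpact."""


class EcoimpactError(Exception):
    """Base class for all ecoimpact errors."""


class ShapeError(EcoimpactError):
    """An array argument has an incompatible shape."""


class InvalidTransformError(EcoimpactError):
    """A parameter transform violates its contract (e.g. zeta(0) != 0)."""


class UnknownTransformError(EcoimpactError, KeyError):
    """A registry name does not resolve to a registered transform."""


class DomainEvaluationError(EcoimpactError):
    """An expression or model could not be evaluated at the given point.

    Carries the offending node or population index when available.
    """

    def __init__(self, message, node=None, population=None):
        super().__init__(message)
        self.node = node
        self.population = population


class SingularityError(EcoimpactError):
    """A parameter derivation hit a singular point (e.g. c_jk <= 0)."""

    def __init__(self, message, indices=None):
        super().__init__(message)
        self.indices = indices


class SingularMatrixError(EcoimpactError):
    """A linear fixed-point system is singular or too ill-conditioned."""


class SimulationError(EcoimpactError):
    """Numerical integration failed; carries the last valid state/time."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class PlateauError(EcoimpactError):
    """A strain did not reach a growth plateau within the horizon."""

    def __init__(self, message, strain=None):
        super().__init__(message)
        self.strain = strain


class ConvergenceError(EcoimpactError):
    """An iterative solver did not converge."""
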