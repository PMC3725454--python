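"""Exception hierarchy shared across the package."""


class SevsemError(Exception):
    """Base class for all package errors."""


class ModelSyntaxError(SevsemError):
    """Model-definition text could not be parsed; message names the line."""


class SpecificationError(SevsemError):
    """A structurally invalid model (duplicate parameters, unknown variables,
    contradictory fixed values)."""


class IdentificationError(SevsemError):
    """Model fails an identification requirement (scale-setting rule,
    negative degrees of freedom, rank-deficient Jacobian)."""


class NotPositiveDefiniteError(SevsemError):
    """A matrix required to be positive definite is not."""


class ConvergenceError(SevsemError):
    """Optimizer failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class SaturatedModelError(SevsemError):
    """Statistic undefined at zero degrees of freedom."""


class InputError(SevsemError):
    """Malformed user input (CSV layout, value ranges)."""


class InfeasibleMomentsError(SevsemError):
    """Requested skew/kurtosis pair or correlation outside the feasible region."""
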