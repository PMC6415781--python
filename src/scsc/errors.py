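"""Exception and warning types shared across the package."""


class ScscError(Exception):
    """Base class for all package-specific errors."""


class InputError(ScscError, ValueError):
    """Invalid user input (shapes, values, file contents)."""


class ZeroDegreeError(InputError):
    """A state has zero total dissimilarity to every other state.

    The generalized eigenproblem is undefined for such a state; remove or
    merge duplicate states before solving.
    """


class ConvergenceError(ScscError, RuntimeError):
    """Eigensolver residual exceeded the requested tolerance."""

    def __init__(self, message: str, worst_residual: float = float("nan")):
        super().__init__(message)
        self.worst_residual = worst_residual


class DegenerateSplitError(ScscError, ValueError):
    """A scalar field is constant and cannot be bifurcated."""


class PipelineError(ScscError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class DuplicateStateWarning(UserWarning):
    """Two states are coincident (zero dissimilarity); treated as duplicates."""
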