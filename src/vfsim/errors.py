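"""Exception hierarchy for the vocal-fold FSI pipeline."""


class VfsimError(Exception):
    """Base class for all package-specific failures."""


class MeshGenerationError(VfsimError):
    """Raised when a parameter combination yields a degenerate mesh.

    The message names the violated geometric constraint.
    """


class InvertedElementError(VfsimError):
    """An element's deformation gradient has non-positive determinant."""

    def __init__(self, element_id: int, detF: float):
        self.element_id = int(element_id)
        self.detF = float(detF)
        super().__init__(
            f"inverted element {element_id}: det(F) = {detF:.3e} <= 0"
        )


class ConvergenceError(VfsimError):
    """An iterative solve failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history=None):
        self.residual_history = list(residual_history or [])
        if self.residual_history:
            message += f" (residuals: {self.residual_history})"
        super().__init__(message)


class CFLError(VfsimError):
    """Advective CFL number too large for the chosen time step."""


class ConfigError(VfsimError):
    """Configuration file is malformed, has unknown keys, or violates invariants."""
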