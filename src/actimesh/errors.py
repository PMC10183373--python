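"""Exception hierarchy."""


class ActimeshError(Exception):
    """Base class for all package errors."""


class InvalidMeshError(ActimeshError):
    """Mesh violates a structural invariant (open surface, non-manifold...)."""


class InvalidGeometryError(ActimeshError):
    """Geometric precondition violated (e.g. ray origin outside the target)."""


class DegenerateVertexError(ActimeshError):
    """A vertex normal could not be defined (all incident faces degenerate)."""


class RemeshError(ActimeshError):
    """Remeshing could not satisfy the requested edge-length bounds."""


class DeformationError(ActimeshError):
    """Mesh evolution failed; carries the last valid mesh if available."""

    def __init__(self, message, last_mesh=None):
        super().__init__(message)
        self.last_mesh = last_mesh


class GenerationError(ActimeshError):
    """Synthetic phantom generation failed (e.g. infeasible packing)."""


class TrainingError(ActimeshError):
    """Network training diverged."""


class FormatError(ActimeshError):
    """A file could not be read unambiguously."""
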