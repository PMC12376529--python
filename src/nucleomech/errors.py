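"""Exception hierarchy for nucleomech."""


class NucleomechError(Exception):
    """Base class for all package errors."""


class MeshStructureError(NucleomechError):
    """The mesh violates a structural requirement (non-manifold, open, ...)."""


class NumericalDegeneracyError(NucleomechError):
    """A geometric quantity degenerated (zero-length edge, zero-area face,
    coincident vertices inside the hard-core radius)."""


class IntegrationError(NucleomechError):
    """The time integration failed (non-finite forces, step collapse)."""

    def __init__(self, message, time=None, max_force=None):
        super().__init__(message)
        self.time = time
        self.max_force = max_force


class SegmentationError(NucleomechError):
    """Image segmentation could not find a foreground object."""


class QualityError(NucleomechError):
    """A quantification failed its data-quality gate (e.g. too many
    excluded pixels in a ratio map)."""


class FitError(NucleomechError):
    """A model fit did not converge or the data violate its assumptions."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateInputError(NucleomechError):
    """Input is constant or otherwise carries no usable signal."""
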