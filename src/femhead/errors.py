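"""Exception hierarchy for the femoral-head morphometry pipeline.

Every stage raises a subclass of :class:`FemheadError` so the pipeline
driver can report which stage failed while preserving partial outputs.
"""


class FemheadError(Exception):
    """Base class for all package errors."""


class FormatError(FemheadError):
    """Unreadable or unsupported volume file."""


class MetadataError(FemheadError):
    """Required metadata (e.g. voxel size) missing and not overridden."""


class ParameterError(FemheadError):
    """Invalid pipeline parameter value."""


class GeometryError(FemheadError):
    """Geometrically impossible request (degenerate axes, centre outside volume...)."""


class DegenerateStructureError(FemheadError):
    """Structure too degenerate to analyse (single phase, too few surface points)."""


class ConvergenceError(FemheadError):
    """Iterative fit failed to converge."""


class EmptyMaskError(FemheadError):
    """An operation received or produced an empty mask where bone was required."""


class MaskConsistencyError(FemheadError):
    """Mask containment violated (e.g. trabecular mask outside whole-bone mask)."""

    def __init__(self, message: str, violating_voxels: int = 0):
        super().__init__(message)
        self.violating_voxels = violating_voxels


class EmptyRegionError(FemheadError):
    """A VOI contained no voxels."""


class InsufficientInputError(FemheadError):
    """Too few inputs (e.g. fewer than two drawn contour slices)."""


class PhantomSpecError(FemheadError):
    """Invalid synthetic-phantom specification."""


class ConsistencyError(FemheadError):
    """Mismatched geometry or region sets between inputs."""
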