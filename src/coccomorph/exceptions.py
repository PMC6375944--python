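"""Exception hierarchy for coccomorph."""


class CoccomorphError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(CoccomorphError, ValueError):
    """A parametric spec violates one of its invariants."""


class UnresolvableSegmentsError(CoccomorphError, ValueError):
    """Voxel size too coarse for the inter-segment gaps to survive voxelization."""


class PackingError(CoccomorphError, RuntimeError):
    """Coccoliths could not be placed on the sphere without overlap."""


class MetadataError(CoccomorphError, IOError):
    """A volume file is missing required metadata (e.g. the voxel size)."""


class MeasurementError(CoccomorphError, RuntimeError):
    """A morphometric operator could not produce a measurement."""


class OrientationError(MeasurementError):
    """Principal-axis orientation is ambiguous (near-degenerate inertia tensor)."""


class EmptyVolumeError(MeasurementError):
    """No voxels above the isovalue."""


class FitError(CoccomorphError, ValueError):
    """A regression / conic fit failed or is degenerate."""
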