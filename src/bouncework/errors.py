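"""Exception hierarchy shared across the package."""


class BounceworkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BounceworkError):
    """A trial file is malformed (missing column, bad header...)."""


class UnitError(BounceworkError):
    """A file header declares units other than the SI units expected."""


class SamplingError(BounceworkError):
    """Timestamps are not uniform within tolerance."""


class MappingError(BounceworkError):
    """Marker/analog labels could not be mapped to the canonical names."""


class ParameterError(BounceworkError):
    """An argument is outside its valid domain."""


class GeometryError(BounceworkError):
    """Marker geometry is degenerate (zero-length segment, gap...)."""


class SegmentationError(BounceworkError):
    """Gait segmentation failed or produced unusable strides."""


class GaitAssumptionError(BounceworkError):
    """The running assumption (no double support) is violated."""


class AlignmentError(BounceworkError):
    """Per-stride quantities were computed on mismatched stride sets."""


class DegenerateFitError(BounceworkError):
    """The regression design matrix is rank deficient."""


class InfeasibleParametersError(BounceworkError):
    """Simulation parameters produce physically impossible gait."""


class MissingDependencyError(BounceworkError):
    """An optional third-party dependency is not installed."""
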