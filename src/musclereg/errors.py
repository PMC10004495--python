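"""Exception hierarchy shared across the package."""


class MuscleRegError(Exception):
    """Base class for all musclereg errors."""


class FormatError(MuscleRegError):
    """A file on disk is not a volume we can interpret (wrong dimensionality, dtype...)."""


class GeometryMismatchError(MuscleRegError):
    """Two volumes that must share grid shape/spacing/origin do not."""


class SequenceGapError(MuscleRegError):
    """Consecutive longitudinal sequences neither overlap nor abut."""


class ConfigurationError(MuscleRegError):
    """An invalid parameter combination (e.g. nodal spacing larger than the image)."""


class ThresholdingError(MuscleRegError):
    """The body-intensity histogram does not expose two tissue modes; a manual
    muscle/fat threshold must be supplied through the configuration."""


class CoverageError(MuscleRegError):
    """A displacement node grid does not cover the geometry being interpolated."""


class NumericalError(MuscleRegError):
    """Registration diverged or produced non-finite quantities."""


class EmptySegmentationError(MuscleRegError):
    """A distance between voxel sets is undefined because one set is empty."""
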