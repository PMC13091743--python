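"""Exception and warning types used across the package."""


class ZonelineError(Exception):
    """Base class for all package-specific errors."""


class SchemaValidationError(ZonelineError):
    """Label data contains codes not present in the schema."""


class GeometryMismatchError(ZonelineError):
    """Two volumes that must share a grid do not."""


class ProbabilityNormalisationError(ZonelineError):
    """Per-voxel class probabilities deviate from 1 beyond tolerance."""


class EmptyStructureError(ZonelineError):
    """A metric that requires a non-empty structure received an empty one."""


class NoUrethraError(ZonelineError):
    """No slice carries any urethra probability; a centerline cannot be fitted."""


class EmptyProstateWarning(UserWarning):
    """The extracted prostate mask is empty."""


class ZoneFallbackWarning(UserWarning):
    """Zone assignment hit a degenerate configuration and fell back."""


class UniformWeightWarning(UserWarning):
    """All centerline fit weights were zero; uniform weights were used."""


class EmptyZoneWarning(UserWarning):
    """A phantom zone-partition parameter left one zone without voxels."""
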