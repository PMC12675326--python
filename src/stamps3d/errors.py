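"""Exception types raised across the pipeline.

All inherit from :class:`Stamps3dError` (a ``ValueError``) so callers can
catch pipeline-specific failures without masking programming errors.
"""


class Stamps3dError(ValueError):
    """Base class for all stamps3d errors."""


class InfeasibleSpeckleSpec(Stamps3dError):
    """Speckle density cannot be realised (>= 1 or placement cannot terminate)."""


class InvalidGeometry(Stamps3dError):
    """Non-positive or inconsistent insole dimensions."""


class BumpOutsideInsole(Stamps3dError):
    """A deformation bump centre lies outside the insole outline."""


class SurfaceNotVisible(Stamps3dError):
    """The insole surface is not fully contained in a camera view."""


class SubsetOutsideImage(Stamps3dError):
    """A correlation subset (plus search margin) does not fit in the image."""


class DegenerateTriangulation(Stamps3dError):
    """Stereo rays are near-parallel or the baseline is zero."""


class CorrelationFailure(Stamps3dError):
    """Fewer than the required fraction of grid nodes correlated successfully."""

    def __init__(self, message, quality_map=None):
        super().__init__(message)
        self.quality_map = quality_map


class AmbiguousOrientation(Stamps3dError):
    """Outline too close to circular to orient without a heel hint."""


class EmptyStrainField(Stamps3dError):
    """No valid nodes remain for strain evaluation."""


class InvalidTemplateConfig(Stamps3dError):
    """Mask template fractions overlap or do not partition the foot domain."""


class RegistrationFailed(Stamps3dError):
    """Outline too degenerate to register the mask template."""


class UnmappedRegion(Stamps3dError):
    """A pressure-table column does not match any known anatomical region."""


class InvalidPressure(Stamps3dError):
    """Negative pressure value in an input table."""


class InsufficientPairs(Stamps3dError):
    """Too few paired strain/pressure points for a correlation."""


class InvalidEffectProfile(Stamps3dError):
    """Synthetic study effect profile contains negative truths or misses regions."""
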