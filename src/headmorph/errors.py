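"""Exception hierarchy shared across the package."""


class HeadmorphError(Exception):
    """Base class for all headmorph errors."""


class VolumeLoadError(HeadmorphError):
    """A NIfTI volume could not be read (missing file, bad payload, bad affine)."""


class OrientationError(HeadmorphError):
    """A volume cannot be brought to canonical orientation without a prior rigid transform."""


class GridMismatchError(HeadmorphError):
    """Two volumes expected on the same voxel grid do not share one."""


class PhantomSpecError(HeadmorphError):
    """A phantom specification is geometrically or statistically invalid."""


class EmptyPlaneError(HeadmorphError):
    """A measurement plane contains no foreground."""


class EmptyIsosurfaceError(HeadmorphError):
    """No voxel of the masked field exceeds the requested iso level."""


class CollinearityError(HeadmorphError):
    """Design matrix columns are linearly dependent."""


class SingularityError(HeadmorphError):
    """A within-group covariance matrix is singular."""


class ConvergenceError(HeadmorphError):
    """An iterative fit failed to converge within its iteration cap."""
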