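"""Head-circumference planimetry in the standardized axial plane.

The measurement emulates a tape measure read off MRI: the five tissue
probability maps are combined into a head probability, smoothed (4 mm FWHM
Gaussian by default), binarized at 0.5, and the axial slice at world z = 0 —
through the mid-forehead and the occiput on a standard-aligned head — is
measured for perimeter (head circumference), primary length and width, the
cephalic index, and 2D head/intracranial/brain areas.

Perimeter estimation uses corner-weighted chain coding of the traced outer
boundary (straight step = pixel spacing, diagonal step = sqrt(2) x spacing)
with a global 0.95 digitization-bias correction; against continuous circles
and ellipses this is accurate to ~2% at 1 mm resolution.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .errors import EmptyPlaneError, HeadmorphError
from .volume_io import BinaryMask, ScalarVolume, TissueSet, require_same_grid

__all__ = [
    "MeasurementPlane",
    "CircumferenceResult",
    "ShapeClass",
    "PlaneMetrics",
    "head_probability",
    "head_mask",
    "extract_plane",
    "measure_circumference",
    "cephalic_index",
    "plane_areas",
    "measure_plane_metrics",
    "CHAIN_CODE_CORRECTION",
]

#: Global correction for the digitization bias of (1, sqrt(2))-weighted chain
#: coding, which overestimates smooth contours by ~5.5% on average.
CHAIN_CODE_CORRECTION = 0.95

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class MeasurementPlane:
    """A 2D axial slice: values indexed [x, y], pixel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float]
    world_z: float

    def __post_init__(self):
        if min(self.spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[0] * self.spacing[1]


class ShapeClass(enum.Enum):
    """Conventional craniometric head-shape classes by cephalic index."""

    OUT_OF_RANGE_LOW = "out_of_range_low"
    DOLICHOCEPHALIC = "dolichocephalic"
    MESOCEPHALIC = "mesocephalic"
    BRACHYCEPHALIC = "brachycephalic"
    HYPERBRACHYCEPHALIC = "hyperbrachycephalic"
    OUT_OF_RANGE_HIGH = "out_of_range_high"


@dataclass(frozen=True)
class CircumferenceResult:
    circumference_cm: float
    length_cm: float
    width_cm: float
    degenerate: bool = False


@dataclass(frozen=True)
class PlaneMetrics:
    """Complete 2D metric battery for one subject's measurement plane."""

    circumference_cm: float
    length_cm: float
    width_cm: float
    cephalic_index: float
    shape_class: ShapeClass
    head_area_cm2: float
    icv_area_cm2: float
    brain_area_cm2: float
    world_z: float
    degenerate: bool = False


def head_probability(ts: TissueSet) -> ScalarVolume:
    """Per-voxel sum of all five tissue probabilities, clipped to [0, 1]."""
    grid = require_same_grid(*ts.volumes().values())
    total = np.zeros(grid.shape, dtype=np.float64)
    for vol in ts.volumes().values():
        total += vol.values
    return ScalarVolume(grid=grid, values=np.clip(total, 0.0, 1.0), is_probability=True)


def smooth_probability(vol: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    if fwhm_mm <= 0:
        raise HeadmorphError("smoothing FWHM must be positive")
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vol.grid.spacing
    smoothed = ndimage.gaussian_filter(np.asarray(vol.values, dtype=np.float64), sigma=sigma_vox)
    return ScalarVolume(grid=vol.grid, values=np.clip(smoothed, 0.0, 1.0), is_probability=True)


def head_mask(vol: ScalarVolume, fwhm_mm: float = 4.0, threshold: float = 0.5) -> BinaryMask:
    """Gaussian-smooth a probability volume and binarize it strictly above ``threshold``."""
    smoothed = smooth_probability(vol, fwhm_mm)
    return BinaryMask(grid=vol.grid, values=smoothed.values > threshold)


def extract_plane(obj: ScalarVolume | BinaryMask, target_world_z: float = 0.0) -> MeasurementPlane:
    """The axial slice whose world z is nearest ``target_world_z``.

    Ties between two equidistant slices break toward inferior (smaller z).
    The volume must be in canonical orientation.
    """
    grid = obj.grid
    if not grid.is_canonical():
        raise HeadmorphError("extract_plane requires a canonical (axis-aligned) volume")
    zs = grid.axis_world_coords(2)
    half = grid.spacing[2] / 2.0
    if target_world_z < zs.min() - half or target_world_z > zs.max() + half:
        raise HeadmorphError(
            f"target z={target_world_z} mm outside volume extent [{zs.min()}, {zs.max()}] mm"
        )
    dist = np.abs(zs - target_world_z)
    # stable argmin returns the first (smaller-z) slice on exact ties
    k = int(np.argmin(dist))
    return MeasurementPlane(
        values=np.asarray(obj.values[:, :, k]),
        spacing=(float(grid.spacing[0]), float(grid.spacing[1])),
        world_z=float(zs[k]),
    )


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace of the (single) foreground component.

    Returns the closed sequence of boundary pixels in order; a single isolated
    pixel yields a length-1 sequence.
    """
    padded = np.pad(mask, 1)
    coords = np.argwhere(padded)
    start = tuple(coords[np.lexsort((coords[:, 1], coords[:, 0]))[0]])
    backtrack = (start[0], start[1] - 1)  # west of the first raster-scan pixel
    boundary = [start]
    current, prev_bg = start, backtrack
    first_move = None
    while True:
        offset = (prev_bg[0] - current[0], prev_bg[1] - current[1])
        try:
            k0 = _MOORE.index(offset)
        except ValueError:  # pragma: no cover - defensive
            k0 = 0
        nxt = None
        for step in range(1, 9):
            cand_off = _MOORE[(k0 + step) % 8]
            cand = (current[0] + cand_off[0], current[1] + cand_off[1])
            if padded[cand]:
                nxt = cand
                break
            prev_bg = cand
        if nxt is None:  # isolated pixel
            return boundary
        move = (current, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:  # Jacob's stopping criterion
            boundary.pop()  # the re-entered start pixel was appended last iteration
            return boundary
        boundary.append(nxt)
        current = nxt


def _chain_perimeter(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    boundary = _trace_boundary(mask)
    if len(boundary) < 2:
        return 0.0
    pts = np.array(boundary + [boundary[0]], dtype=float)
    steps = np.diff(pts, axis=0) * np.array(spacing)
    return CHAIN_CODE_CORRECTION * float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def _largest_filled_component(values: np.ndarray) -> np.ndarray:
    labels, n = skmeasure.label(values, connectivity=2, return_num=True)
    if n == 0:
        raise EmptyPlaneError("measurement plane contains no foreground pixels")
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        values = labels == keep
    else:
        values = labels > 0
    return ndimage.binary_fill_holes(values)


def measure_circumference(plane: MeasurementPlane) -> CircumferenceResult:
    """Perimeter, primary length, and width of the head region in a binary plane.

    The largest 8-connected component is kept and its interior holes filled;
    the perimeter is the bias-corrected chain-code length of its traced outer
    boundary, and length/width are the major/minor axis lengths of the ellipse
    with the same normalized second central moments as the region.
    """
    values = np.asarray(plane.values)
    if values.dtype != bool:
        values = values > 0.5
    region = _largest_filled_component(values)
    perimeter_mm = _chain_perimeter(region, plane.spacing)
    props = skmeasure.regionprops(region.astype(np.uint8), spacing=plane.spacing)[0]
    length_mm = float(props.axis_major_length)
    width_mm = float(props.axis_minor_length)
    degenerate = int(region.sum()) == 1 or width_mm == 0.0
    return CircumferenceResult(
        circumference_cm=perimeter_mm / 10.0,
        length_cm=length_mm / 10.0,
        width_cm=width_mm / 10.0,
        degenerate=degenerate,
    )


def cephalic_index(width_cm: float, length_cm: float) -> tuple[float, ShapeClass]:
    """CI = 100 * width / length and its craniometric class.

    Classes sit on half-open intervals [70, 75), [75, 80), [80, 85), [85, 90);
    a boundary value is assigned to the class above it.
    """
    if width_cm <= 0:
        raise HeadmorphError("width must be positive")
    if width_cm > length_cm:
        raise HeadmorphError("width exceeds length; order the axes before computing CI")
    ci = 100.0 * width_cm / length_cm
    if ci < 70.0:
        cls = ShapeClass.OUT_OF_RANGE_LOW
    elif ci < 75.0:
        cls = ShapeClass.DOLICHOCEPHALIC
    elif ci < 80.0:
        cls = ShapeClass.MESOCEPHALIC
    elif ci < 85.0:
        cls = ShapeClass.BRACHYCEPHALIC
    elif ci < 90.0:
        cls = ShapeClass.HYPERBRACHYCEPHALIC
    else:
        cls = ShapeClass.OUT_OF_RANGE_HIGH
    return ci, cls


def _combined(ts: TissueSet, names) -> ScalarVolume:
    grid = require_same_grid(*ts.volumes().values())
    total = np.zeros(grid.shape, dtype=np.float64)
    for name in names:
        total += getattr(ts, name).values
    return ScalarVolume(grid=grid, values=np.clip(total, 0.0, 1.0), is_probability=True)


def plane_areas(
    ts: TissueSet,
    target_world_z: float = 0.0,
    fwhm_mm: float = 4.0,
    threshold: float = 0.5,
    probabilistic: bool = False,
) -> tuple[float, float, float]:
    """(head, ICV, brain) areas in cm^2 in the measurement plane.

    Head combines all five tissues, ICV combines GM+WM+CSF, brain GM+WM.  Each
    combination is smoothed and binarized exactly like :func:`head_mask` and
    the area is foreground pixel count x pixel area.  With
    ``probabilistic=True`` the unsmoothed probability sum over the plane is
    used instead of a pixel count.
    """
    combos = {
        "head": TissueSet.TISSUES,
        "icv": ("gm", "wm", "csf"),
        "brain": ("gm", "wm"),
    }
    areas = []
    for names in combos.values():
        vol = _combined(ts, names)
        if probabilistic:
            plane = extract_plane(vol, target_world_z)
            areas.append(float(plane.values.sum()) * plane.pixel_area_mm2 / 100.0)
        else:
            mask = head_mask(vol, fwhm_mm=fwhm_mm, threshold=threshold)
            plane = extract_plane(mask, target_world_z)
            areas.append(float(np.count_nonzero(plane.values)) * plane.pixel_area_mm2 / 100.0)
    return tuple(areas)


def measure_plane_metrics(
    ts: TissueSet,
    target_world_z: float = 0.0,
    fwhm_mm: float = 4.0,
    threshold: float = 0.5,
) -> PlaneMetrics:
    """Full 2D battery: circumference, axes, cephalic index + class, areas."""
    mask = head_mask(head_probability(ts), fwhm_mm=fwhm_mm, threshold=threshold)
    plane = extract_plane(mask, target_world_z)
    circ = measure_circumference(plane)
    ci, cls = cephalic_index(max(circ.width_cm, 1e-9), max(circ.length_cm, circ.width_cm, 1e-9))
    head_a, icv_a, brain_a = plane_areas(
        ts, target_world_z=target_world_z, fwhm_mm=fwhm_mm, threshold=threshold
    )
    return PlaneMetrics(
        circumference_cm=circ.circumference_cm,
        length_cm=circ.length_cm,
        width_cm=circ.width_cm,
        cephalic_index=ci,
        shape_class=cls,
        head_area_cm2=head_a,
        icv_area_cm2=icv_a,
        brain_area_cm2=brain_a,
        world_z=plane.world_z,
        degenerate=circ.degenerate,
    )
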