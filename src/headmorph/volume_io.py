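"""Voxel volumes, grids, and NIfTI I/O.

All downstream measurement code operates on the types defined here.  The world
coordinate convention is RAS-like and fixed throughout the package:
``+x`` = subject right, ``+y`` = anterior, ``+z`` = superior.  Laterality logic
(left/right splits, asymmetry indices) depends on this convention, so volumes
coming from disk should pass through :func:`canonicalize` before measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, OrientationError, VolumeLoadError

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "BinaryMask",
    "TissueSet",
    "TissueValidationReport",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "canonicalize",
    "validate_tissue_set",
    "sample_world",
]

#: Per-voxel tolerance on the five-tissue probability sum.
TISSUE_SUM_TOLERANCE = 0.05


@dataclass(frozen=True)
class VoxelGrid:
    """A regular voxel lattice with an affine index→world map (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def axis_world_coords(self, axis: int) -> np.ndarray:
        """World coordinate along ``axis`` for each slice index (canonical grids)."""
        return self.affine[axis, 3] + np.arange(self.shape[axis]) * self.affine[axis, axis]

    def is_canonical(self, tol: float = 1e-3) -> bool:
        """Axis-aligned with positive spacing on the diagonal."""
        lin = self.affine[:3, :3]
        off = lin - np.diag(np.diag(lin))
        return bool(np.all(np.diag(lin) > 0) and np.max(np.abs(off)) <= tol * np.max(np.abs(lin)))

    def same_as(self, other: "VoxelGrid", tol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)


@dataclass
class ScalarVolume:
    """A scalar field on a :class:`VoxelGrid`; probability maps live in [0, 1]."""

    grid: VoxelGrid
    values: np.ndarray
    is_probability: bool = True

    def __post_init__(self):
        values = np.asarray(self.values)
        if tuple(values.shape) != self.grid.shape:
            raise ValueError(f"values shape {values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        self.values = values

    def probabilistic_sum(self) -> float:
        return float(self.values.sum(dtype=np.float64))


@dataclass
class BinaryMask:
    """A boolean field on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values)
        if tuple(values.shape) != self.grid.shape:
            raise ValueError(f"mask shape {values.shape} != grid shape {self.grid.shape}")
        self.values = values.astype(bool)


@dataclass
class TissueSet:
    """Five co-registered tissue probability maps: GM, WM, CSF, bone, soft tissue."""

    gm: ScalarVolume
    wm: ScalarVolume
    csf: ScalarVolume
    bone: ScalarVolume
    soft: ScalarVolume

    TISSUES = ("gm", "wm", "csf", "bone", "soft")

    @property
    def grid(self) -> VoxelGrid:
        return self.gm.grid

    def volumes(self) -> dict[str, ScalarVolume]:
        return {name: getattr(self, name) for name in self.TISSUES}


@dataclass
class TissueValidationReport:
    """Result of :func:`validate_tissue_set`; report-only, never raises."""

    grid_mismatches: list[str] = field(default_factory=list)
    n_sum_violations: int = 0
    max_sum: float = 0.0

    @property
    def passed(self) -> bool:
        return not self.grid_mismatches and self.n_sum_violations == 0


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types for bad payloads
        raise VolumeLoadError(f"cannot read NIfTI volume {path}: {exc}") from exc
    affine = img.affine
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise VolumeLoadError(f"non-invertible affine in {path}")
    return img


def read_volume(path, probability: bool = True) -> ScalarVolume:
    """Read a NIfTI-1 scalar volume.

    Probability maps (``probability=True``) are clipped to [0, 1] on load; a
    warning is emitted if more than 0.1% of voxels were out of range, which
    usually indicates the file is not a probability map at all.
    """
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeLoadError(f"expected a 3D volume in {path}, got shape {data.shape}")
    if probability:
        out_of_range = np.count_nonzero((data < 0) | (data > 1))
        if out_of_range > 1e-3 * data.size:
            warnings.warn(
                f"{path}: {out_of_range} voxels outside [0, 1] were clipped",
                stacklevel=2,
            )
        data = np.clip(data, 0.0, 1.0)
    grid = VoxelGrid(shape=data.shape, affine=np.asarray(img.affine, dtype=float))
    return ScalarVolume(grid=grid, values=data, is_probability=probability)


def read_mask(path) -> BinaryMask:
    vol = read_volume(path, probability=False)
    return BinaryMask(grid=vol.grid, values=vol.values > 0.5)


def write_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def _check_not_oblique(affine: np.ndarray, tol: float = 1e-3) -> None:
    lin = affine[:3, :3]
    norms = np.linalg.norm(lin, axis=0)
    for j in range(3):
        col = np.abs(lin[:, j]) / norms[j]
        if np.sort(col)[-2] > tol:  # second-largest direction cosine
            raise OrientationError(
                "volume is oblique (off-axis rotation exceeds tolerance); "
                "apply a rigid registration to standard alignment before canonicalizing"
            )


def canonicalize(vol: ScalarVolume, iso_mm: float = 1.0) -> ScalarVolume:
    """Reorient a volume to the canonical +x right / +y anterior / +z superior axes.

    Axis order and flips are corrected losslessly (world coordinates of every
    voxel are preserved).  Anisotropic grids are then resampled trilinearly to
    ``iso_mm`` isotropic spacing; values outside the original field of view are
    treated as zero.  Oblique affines are rejected: rigid registration is an
    upstream responsibility.
    """
    _check_not_oblique(vol.grid.affine)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), vol.grid.affine)
    ornt = nib.orientations.io_orientation(img.affine)
    data = nib.orientations.apply_orientation(img.get_fdata(), ornt)
    affine = img.affine @ nib.orientations.inv_ornt_aff(ornt, img.shape)
    grid = VoxelGrid(shape=data.shape, affine=affine)

    spacing = grid.spacing
    if np.ptp(spacing) > 1e-6 * spacing.max():
        # resample to isotropic spacing, keeping the world origin of voxel (0,0,0)
        origin = affine[:3, 3].copy()
        extent = (np.array(data.shape) - 1) * spacing
        new_shape = np.maximum(np.ceil(extent / iso_mm).astype(int) + 1, 1)
        new_affine = np.eye(4)
        new_affine[:3, :3] = np.eye(3) * iso_mm
        new_affine[:3, 3] = origin
        # voxel coords of the new grid expressed in old voxel coords
        coords = np.meshgrid(
            *[np.arange(n) * iso_mm / spacing[i] for i, n in enumerate(new_shape)],
            indexing="ij",
        )
        data = ndimage.map_coordinates(data, coords, order=1, mode="constant", cval=0.0)
        grid = VoxelGrid(shape=data.shape, affine=new_affine)

    if vol.is_probability:
        data = np.clip(data, 0.0, 1.0)
    return ScalarVolume(grid=grid, values=data, is_probability=vol.is_probability)


def sample_world(vol: ScalarVolume, points_xyz: np.ndarray) -> np.ndarray:
    """Trilinear sample of the volume at world-mm coordinates (0 outside)."""
    idx = vol.grid.world_to_index(points_xyz)
    return ndimage.map_coordinates(
        np.asarray(vol.values, dtype=np.float64), idx.T, order=1, mode="constant", cval=0.0
    )


def validate_tissue_set(ts: TissueSet) -> TissueValidationReport:
    """Check grid identity across the five maps and the per-voxel probability sum.

    The report lists maps whose grid differs from the GM grid, and counts the
    voxels where the five probabilities sum above ``1 + TISSUE_SUM_TOLERANCE``.
    """
    report = TissueValidationReport()
    ref = ts.gm.grid
    for name, vol in ts.volumes().items():
        if not vol.grid.same_as(ref):
            report.grid_mismatches.append(name)
    if not report.grid_mismatches:
        total = np.zeros(ref.shape, dtype=np.float64)
        for vol in ts.volumes().values():
            total += vol.values
        report.max_sum = float(total.max()) if total.size else 0.0
        report.n_sum_violations = int(np.count_nonzero(total > 1.0 + TISSUE_SUM_TOLERANCE))
    return report


def require_same_grid(*objs) -> VoxelGrid:
    """Return the shared grid of the arguments or raise :class:`GridMismatchError`."""
    ref = objs[0].grid
    for obj in objs[1:]:
        if not obj.grid.same_as(ref):
            raise GridMismatchError("volumes do not share one voxel grid")
    return ref
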