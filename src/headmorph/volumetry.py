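"""Intracranial compartment volumetry, laterality, and ventricular surface area.

Volumes are probabilistic: the volume of a tissue is the sum of its per-voxel
probabilities times the voxel volume (no thresholding).  Total CSF is split
into ventricular and subarachnoid parts by intersecting the CSF probability
map with a standard-space binary ventricle mask:
``ventricular = sum(csf * mask)``, ``subarachnoid = total - ventricular``.
Hemispheric asymmetry uses the world midline x = 0 (+x = subject right):
``AI = (right - left) / (right + left)``.  The ventricular surface is the
0.5-isosurface of the masked CSF probability field, triangulated by marching
cubes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

from .errors import EmptyIsosurfaceError, HeadmorphError
from .volume_io import BinaryMask, ScalarVolume, TissueSet, require_same_grid

__all__ = [
    "CompartmentVolumes",
    "HemisphereSplit",
    "LateralityMetrics",
    "SurfaceMesh",
    "probabilistic_volume",
    "compartment_volumes",
    "hemispheric_asymmetry",
    "laterality_metrics",
    "ventricular_surface_area",
    "export_mesh",
]


@dataclass(frozen=True)
class CompartmentVolumes:
    """The 3D compartment battery in ml; additivity identities hold exactly."""

    icv: float
    brain: float
    gm: float
    wm: float
    csf_total: float
    csf_ventricular: float
    csf_subarachnoid: float


@dataclass(frozen=True)
class HemisphereSplit:
    """Left/right probabilistic volumes of one field and derived asymmetry."""

    left_ml: float
    right_ml: float
    ai: float  # NaN when left + right == 0
    absdiff_ml: float


@dataclass(frozen=True)
class LateralityMetrics:
    """Asymmetry battery: ventricular and total CSF splits."""

    ventricular: HemisphereSplit
    total_csf: HemisphereSplit


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated isosurface in world mm with total area in cm^2."""

    vertices: np.ndarray  # (n, 3) world mm
    faces: np.ndarray  # (m, 3) vertex indices
    area_cm2: float


def probabilistic_volume(vol: ScalarVolume) -> float:
    """Sum of probabilities x voxel volume, in ml."""
    return vol.probabilistic_sum() * vol.grid.voxel_volume_mm3 / 1000.0


def compartment_volumes(ts: TissueSet, ventricle_mask: BinaryMask) -> CompartmentVolumes:
    """GM/WM/CSF volumetry with the ventricular/subarachnoid CSF split.

    The ventricular part keeps the CSF probabilities inside the mask (the mask
    gates, it does not re-threshold), so the split is exactly additive.
    """
    grid = require_same_grid(*ts.volumes().values(), ventricle_mask)
    vv = grid.voxel_volume_mm3 / 1000.0
    gm = float(ts.gm.values.sum(dtype=np.float64)) * vv
    wm = float(ts.wm.values.sum(dtype=np.float64)) * vv
    csf_total = float(ts.csf.values.sum(dtype=np.float64)) * vv
    vent = float(ts.csf.values[ventricle_mask.values].sum(dtype=np.float64)) * vv
    return CompartmentVolumes(
        icv=gm + wm + csf_total,
        brain=gm + wm,
        gm=gm,
        wm=wm,
        csf_total=csf_total,
        csf_ventricular=vent,
        csf_subarachnoid=csf_total - vent,
    )


def _hemisphere_weights(vol: ScalarVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (x-index) weights for the left and right hemispheres.

    A voxel whose center lies within half a voxel of the midline contributes
    half of its probability to each side, making the split exactly symmetric
    on midline-aligned grids.
    """
    grid = vol.grid
    if not grid.is_canonical():
        raise HeadmorphError("hemispheric split requires a canonical (axis-aligned) volume")
    x = grid.axis_world_coords(0)
    half = grid.spacing[0] / 2.0
    right = np.where(np.abs(x) < half, 0.5, (x > 0).astype(float))
    left = np.where(np.abs(x) < half, 0.5, (x < 0).astype(float))
    return left, right


def hemispheric_asymmetry(vol: ScalarVolume) -> HemisphereSplit:
    """Left/right probabilistic volumes about x = 0, AI, and absolute difference."""
    left_w, right_w = _hemisphere_weights(vol)
    col_sums = vol.values.sum(axis=(1, 2), dtype=np.float64)
    vv = vol.grid.voxel_volume_mm3 / 1000.0
    left = float(col_sums @ left_w) * vv
    right = float(col_sums @ right_w) * vv
    total = left + right
    ai = (right - left) / total if total > 0 else float("nan")
    return HemisphereSplit(left_ml=left, right_ml=right, ai=ai, absdiff_ml=abs(left - right))


def laterality_metrics(ts: TissueSet, ventricle_mask: BinaryMask) -> LateralityMetrics:
    """Asymmetry of ventricular CSF (masked field) and of total CSF."""
    grid = require_same_grid(ts.csf, ventricle_mask)
    masked = ScalarVolume(
        grid=grid,
        values=ts.csf.values * ventricle_mask.values,
        is_probability=True,
    )
    return LateralityMetrics(
        ventricular=hemispheric_asymmetry(masked),
        total_csf=hemispheric_asymmetry(ts.csf),
    )


def ventricular_surface_area(
    csf: ScalarVolume, ventricle_mask: BinaryMask, iso: float = 0.5
) -> SurfaceMesh:
    """Marching-cubes isosurface of the masked CSF probability field.

    Running on the probability field (not a binarized mask) places the surface
    at sub-voxel positions, so areas converge to the continuous surface.  The
    field is cropped to the mask bounding box (padded by two voxels) before
    triangulation, purely for speed.
    """
    grid = require_same_grid(csf, ventricle_mask)
    field = np.asarray(csf.values, dtype=np.float64) * ventricle_mask.values
    if field.max(initial=0.0) <= iso:
        raise EmptyIsosurfaceError(
            f"no ventricle above iso level {iso}: masked CSF maximum is {field.max(initial=0.0):.3f}"
        )
    nz = np.argwhere(field > 0)
    lo = np.maximum(nz.min(axis=0) - 2, 0)
    hi = np.minimum(nz.max(axis=0) + 3, field.shape)
    sub = field[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    # nudge the level off exact voxel values: fields with plateaus exactly at
    # iso otherwise yield degenerate (non-watertight) triangulations
    level = iso + 1e-6 * max(1.0, abs(iso))
    verts, faces, _, _ = skmeasure.marching_cubes(sub, level=level, spacing=tuple(grid.spacing))
    origin = grid.index_to_world(lo)[0]
    verts = verts + origin
    area = float(skmeasure.mesh_surface_area(verts, faces))
    return SurfaceMesh(vertices=verts, faces=faces, area_cm2=area / 100.0)


def export_mesh(mesh: SurfaceMesh, path) -> None:
    """Write the mesh (mm units) to STL/OBJ/... by file extension."""
    import trimesh

    trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False).export(str(path))
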