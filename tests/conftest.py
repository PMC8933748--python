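import numpy as np
import pytest

from headmorph.phantom import PhantomSpec, ShellThicknesses, Ventricle, generate_phantom
from headmorph.volume_io import ScalarVolume, VoxelGrid


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A fast-to-rasterize head phantom used throughout the unit tests.

    Scaled-down outer geometry with ventricles large enough (relative to the
    partial-volume smoothing) that all measurement tolerances of the
    full-scale phantom still apply.
    """
    base = dict(
        outer_semi_axes=(40.0, 50.0, 35.0),
        shells=ShellThicknesses(3.0, 3.0, 2.5, 3.0),
        ventricle=Ventricle(center_offset=9.0, center_y=0.0, center_z=9.0, semi_axes=(6.0, 16.0, 8.0)),
        pv_sigma=0.8,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(TissueSet, ventricle BinaryMask, PhantomTruth) for the shared test phantom."""
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def asym_phantom():
    """Same phantom with the right ventricle enlarged by 20% per axis."""
    return generate_phantom(small_phantom_spec(right_scale=1.2))


def centered_grid(shape, spacing=1.0) -> VoxelGrid:
    """Canonical grid with the world origin at the central voxel."""
    shape = tuple(int(s) for s in shape)
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = [-(s - 1) / 2.0 * spacing for s in shape]
    return VoxelGrid(shape=shape, affine=affine)


def hc_csf_worked_example():
    """(TissueSet, BinaryMask) whose CSF split is exactly the control-group
    compartments: 18 ml ventricular + 276 ml subarachnoid = 294 ml total."""
    from headmorph.volume_io import BinaryMask, TissueSet

    grid = centered_grid((90, 90, 70))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[30:60, 30:60, 20:50] = True  # 27 000 voxels
    region = np.zeros(grid.shape, dtype=bool)
    region[5:85, 5:85, 5:65] = True  # 384 000 voxels
    csf = np.zeros(grid.shape)
    csf[mask] = 18_000 / mask.sum()
    outside = region & ~mask
    csf[outside] = 276_000 / outside.sum()
    zero = ScalarVolume(grid=grid, values=np.zeros(grid.shape))
    ts = TissueSet(
        gm=zero, wm=zero, csf=ScalarVolume(grid=grid, values=csf), bone=zero, soft=zero
    )
    return ts, BinaryMask(grid=grid, values=mask)


def sphere_volume(radius_mm: float, spacing: float = 1.0, margin: float = 6.0) -> ScalarVolume:
    """Antialiased sphere indicator on a centered grid (for analytic checks)."""
    n = int(2 * np.ceil((radius_mm + margin) / spacing) + 1)
    grid = centered_grid((n, n, n), spacing)
    half = (n - 1) / 2.0 * spacing
    coords = np.arange(n) * spacing - half
    x = coords.reshape(-1, 1, 1)
    y = coords.reshape(1, -1, 1)
    z = coords.reshape(1, 1, -1)
    r = np.sqrt(x**2 + y**2 + z**2)
    values = np.clip(0.5 - (r - radius_mm) / spacing, 0.0, 1.0)
    return ScalarVolume(grid=grid, values=values, is_probability=True)
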