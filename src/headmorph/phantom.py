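"""Synthetic five-tissue head phantoms and metric-level cohort simulation.

The geometric phantom is a nest of concentric ellipsoids — scalp, skull,
subarachnoid CSF, grey matter, white matter — with a pair of ellipsoidal
lateral ventricles (CSF) embedded in the white matter.  Every quantity the
measurement pipeline produces (compartment volumes, the z = 0 plane perimeter
and axes, cephalic index, ventricular surface area, asymmetry index) has a
closed form for this geometry, so the phantom doubles as an analytic oracle.

The metric-level cohort simulator draws per-subject metric vectors from
group-specific multivariate normals, defaulting to the ASD/control summary
statistics of the adult-male study cohort this pipeline targets, so the
statistics and classification stages can be exercised without any imaging.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PhantomSpecError
from .volume_io import BinaryMask, ScalarVolume, TissueSet, VoxelGrid

__all__ = [
    "ShellThicknesses",
    "Ventricle",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "ellipse_perimeter",
    "ellipsoid_surface_area",
    "ellipsoid_volume",
    "analytic_truth",
    "generate_phantom",
    "simulate_metric_cohort",
    "METRIC_COLUMNS",
    "TABLE_PARAMS",
]


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of an ellipsoid with semi-axes a, b, c (mm^3)."""
    return 4.0 / 3.0 * math.pi * a * b * c


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter.

    Accurate to well below 0.01% for any eccentricity a head can have.
    """
    h = ((a - b) / (a + b)) ** 2 if a + b > 0 else 0.0
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def ellipsoid_surface_area(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Thomsen's approximation to the ellipsoid surface area (max error ~1.06%)."""
    ap, bp, cp = a**p, b**p, c**p
    return 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)


@dataclass(frozen=True)
class ShellThicknesses:
    """Shell thicknesses in mm, outermost first; white matter fills the remainder."""

    soft: float = 5.0
    bone: float = 6.0
    csf: float = 3.0
    gm: float = 4.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.soft, self.bone, self.csf, self.gm)


@dataclass(frozen=True)
class Ventricle:
    """One lateral ventricle: an ellipsoid offset from the midline.

    ``center_offset`` is the unsigned distance of the center from the x = 0
    midline; the generator places one ventricle at +offset (right) and one at
    -offset (left).
    """

    center_offset: float = 15.0
    center_y: float = 0.0
    center_z: float = 15.0
    semi_axes: tuple[float, float, float] = (8.0, 25.0, 10.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic head.

    ``outer_semi_axes`` are the scalp ellipsoid semi-axes (a along x = width,
    b along y = length, c along z).  ``right_scale`` multiplies the right
    ventricle's semi-axes to induce a controlled left-right asymmetry
    (1 = mirror symmetric).  ``pv_sigma`` smooths the hard tissue shells into
    probabilistic boundaries, emulating partial-volume effects; ``noise_sd``
    adds Gaussian probability noise.
    """

    outer_semi_axes: tuple[float, float, float] = (80.0, 95.0, 70.0)
    shells: ShellThicknesses = field(default_factory=ShellThicknesses)
    ventricle: Ventricle = field(default_factory=Ventricle)
    right_scale: float = 1.0
    pv_sigma: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    spacing_mm: float = 1.0
    margin_mm: float = 5.0

    def scaled(self, s: float) -> "PhantomSpec":
        """All lengths multiplied by ``s`` (spacing and smoothing untouched)."""
        v = self.ventricle
        return replace(
            self,
            outer_semi_axes=tuple(s * x for x in self.outer_semi_axes),
            shells=ShellThicknesses(*(s * t for t in self.shells.as_tuple())),
            ventricle=Ventricle(
                center_offset=s * v.center_offset,
                center_y=s * v.center_y,
                center_z=s * v.center_z,
                semi_axes=tuple(s * x for x in v.semi_axes),
            ),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["shells"] = ShellThicknesses(**d["shells"])
        v = d["ventricle"]
        v["semi_axes"] = tuple(v["semi_axes"])
        d["ventricle"] = Ventricle(**v)
        d["outer_semi_axes"] = tuple(d["outer_semi_axes"])
        return cls(**d)


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form expected values for every metric the pipeline measures."""

    head_ml: float
    icv_ml: float
    brain_ml: float
    gm_ml: float
    wm_ml: float
    csf_total_ml: float
    csf_ventricular_ml: float
    csf_subarachnoid_ml: float
    csf_ventricular_left_ml: float
    csf_ventricular_right_ml: float
    plane_semi_axes_cm: tuple[float, float]
    circumference_cm: float
    length_cm: float
    width_cm: float
    cephalic_index: float
    head_area_cm2: float
    icv_area_cm2: float
    brain_area_cm2: float
    ventricular_sa_cm2: float
    ventricular_ai: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _nested_semi_axes(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """Semi-axes of the five nested ellipsoid boundaries, outermost first.

    Returns [scalp, skull-outer, csf-outer(=ICV boundary... see below)] —
    precisely: outer surfaces of soft, bone, subarachnoid CSF, GM, and the WM
    region, obtained by successively subtracting shell thicknesses.
    """
    axes = [tuple(float(x) for x in spec.outer_semi_axes)]
    for t in spec.shells.as_tuple():
        prev = axes[-1]
        nxt = tuple(x - t for x in prev)
        if min(nxt) <= 0:
            raise PhantomSpecError(
                f"shells do not nest: subtracting thickness {t} mm from semi-axes {prev} "
                "leaves a non-positive axis"
            )
        axes.append(nxt)
    return axes


def _ventricle_params(spec: PhantomSpec):
    """[(center, semi_axes)] for (left, right) ventricles in world mm."""
    if spec.right_scale <= 0:
        raise PhantomSpecError("right_scale must be > 0")
    v = spec.ventricle
    left = (np.array([-v.center_offset, v.center_y, v.center_z]), np.array(v.semi_axes, float))
    right = (
        np.array([v.center_offset, v.center_y, v.center_z]),
        np.array(v.semi_axes, float) * spec.right_scale,
    )
    return left, right


_UNIT_SPHERE_DIRS = None


def _unit_sphere_dirs(n: int = 512) -> np.ndarray:
    """Deterministic quasi-uniform directions (Fibonacci sphere), cached."""
    global _UNIT_SPHERE_DIRS
    if _UNIT_SPHERE_DIRS is None or len(_UNIT_SPHERE_DIRS) != n:
        k = np.arange(n)
        z = 1.0 - 2.0 * (k + 0.5) / n
        phi = k * math.pi * (3.0 - math.sqrt(5.0))
        r = np.sqrt(1.0 - z**2)
        _UNIT_SPHERE_DIRS = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return _UNIT_SPHERE_DIRS


def _check_ventricles_in_wm(spec: PhantomSpec, wm_axes) -> None:
    wm_axes = np.asarray(wm_axes, float)
    for center, axes in _ventricle_params(spec):
        pts = center + _unit_sphere_dirs() * axes
        q = np.sum((pts / wm_axes) ** 2, axis=1)
        if np.any(q > 1.0):
            raise PhantomSpecError(
                "ventricle ellipsoid is not contained in the white-matter region"
            )


def analytic_truth(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form metric values for a phantom spec.

    Volumes come from nested-ellipsoid differences, the z = 0 plane perimeter
    from Ramanujan's approximation, and the ventricular surface area from
    Thomsen's approximation, each applied per ventricle and summed (the two
    ventricles are disjoint).  The cephalic index is reported as
    100 * minor / major of the plane ellipse, matching the width <= length
    ordering the planimetry stage enforces.
    """
    shells = _nested_semi_axes(spec)
    outer, _, icv_ax, csf_inner_ax, wm_ax = shells
    _check_ventricles_in_wm(spec, wm_ax)
    (lc, la), (rc, ra) = _ventricle_params(spec)

    head = ellipsoid_volume(*outer) / 1000.0
    icv = ellipsoid_volume(*icv_ax) / 1000.0
    sub_csf = (ellipsoid_volume(*icv_ax) - ellipsoid_volume(*csf_inner_ax)) / 1000.0
    gm = (ellipsoid_volume(*csf_inner_ax) - ellipsoid_volume(*wm_ax)) / 1000.0
    v_left = ellipsoid_volume(*la) / 1000.0
    v_right = ellipsoid_volume(*ra) / 1000.0
    vent = v_left + v_right
    wm = ellipsoid_volume(*wm_ax) / 1000.0 - vent
    csf_total = sub_csf + vent
    brain = gm + wm

    a, b = outer[0], outer[1]
    width, length = 2.0 * min(a, b), 2.0 * max(a, b)
    ci = 100.0 * width / length
    sa = sum(
        ellipsoid_surface_area(*axes) for _, axes in ((lc, la), (rc, ra))
    ) / 100.0
    ai = (v_right - v_left) / (v_right + v_left)

    return PhantomTruth(
        head_ml=head,
        icv_ml=icv,
        brain_ml=brain,
        gm_ml=gm,
        wm_ml=wm,
        csf_total_ml=csf_total,
        csf_ventricular_ml=vent,
        csf_subarachnoid_ml=sub_csf,
        csf_ventricular_left_ml=v_left,
        csf_ventricular_right_ml=v_right,
        plane_semi_axes_cm=(a / 10.0, b / 10.0),
        circumference_cm=ellipse_perimeter(a, b) / 10.0,
        length_cm=length / 10.0,
        width_cm=width / 10.0,
        cephalic_index=ci,
        head_area_cm2=math.pi * a * b / 100.0,
        icv_area_cm2=math.pi * icv_ax[0] * icv_ax[1] / 100.0,
        brain_area_cm2=math.pi * csf_inner_ax[0] * csf_inner_ax[1] / 100.0,
        ventricular_sa_cm2=sa,
        ventricular_ai=ai,
    )


def _phantom_grid(spec: PhantomSpec) -> VoxelGrid:
    """Symmetric grid with a voxel exactly at world (0,0,0) and >= margin around."""
    half = np.ceil((np.array(spec.outer_semi_axes) + spec.margin_mm) / spec.spacing_mm)
    shape = (2 * half + 1).astype(int)
    affine = np.eye(4)
    affine[:3, :3] *= spec.spacing_mm
    affine[:3, 3] = -half * spec.spacing_mm
    return VoxelGrid(shape=tuple(shape), affine=affine)


def _ellipsoid_coverage(grid_coords, center, semi_axes, spacing: float) -> np.ndarray:
    """Antialiased ellipsoid rasterization: per-voxel inside fraction in [0, 1].

    The fraction is approximated by a linear ramp over the voxel extent in the
    signed distance to the surface, with the distance linearized from the
    ellipsoid quadratic form.  This keeps rasterized masses within ~0.1% of
    the analytic volume at 1 mm resolution even for small eccentric
    ellipsoids, where voxel-center counting errs by ~1%.
    """
    x, y, z = grid_coords
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    a, b, c = semi_axes
    q = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2
    s = np.sqrt(q)
    grad = np.sqrt((dx / a**2) ** 2 + (dy / b**2) ** 2 + (dz / c**2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, (s - 1.0) * s / grad, -min(semi_axes))
    return np.clip(0.5 - dist / spacing, 0.0, 1.0)


def _ball_footprint(radius_vox: float) -> np.ndarray:
    r = int(math.ceil(radius_vox))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (xx**2 + yy**2 + zz**2) <= radius_vox**2


def generate_phantom(spec: PhantomSpec) -> tuple[TissueSet, BinaryMask, PhantomTruth]:
    """Rasterize a phantom spec into five tissue probability maps.

    Hard tissue-region indicators are smoothed with a Gaussian of ``pv_sigma``
    mm; by linearity the five smoothed maps still sum to at most one, and any
    numerical excess is renormalized away.  Optional zero-mean Gaussian noise
    is added per tissue, clipped to [0, 1], and voxels pushed above unit total
    probability are renormalized.  The returned ventricle truth mask is the
    union of the two ventricle ellipsoids dilated by 2 mm — deliberately
    generous, as standard-space ventricle masks are.
    """
    truth = analytic_truth(spec)  # validates nesting and containment
    shells = _nested_semi_axes(spec)
    grid = _phantom_grid(spec)
    sp = spec.spacing_mm
    coords = [
        (grid.affine[i, 3] + np.arange(grid.shape[i]) * sp).reshape(
            [-1 if j == i else 1 for j in range(3)]
        )
        for i in range(3)
    ]
    origin = np.zeros(3)
    cov = [_ellipsoid_coverage(coords, origin, ax, sp) for ax in shells]
    vent_cov = sum(
        _ellipsoid_coverage(coords, center, axes, sp)
        for center, axes in _ventricle_params(spec)
    )
    vent_cov = np.minimum(vent_cov, 1.0)

    regions = {
        "soft": np.clip(cov[0] - cov[1], 0.0, 1.0),
        "bone": np.clip(cov[1] - cov[2], 0.0, 1.0),
        "gm": np.clip(cov[3] - cov[4], 0.0, 1.0),
        "wm": np.clip(cov[4] - vent_cov, 0.0, 1.0),
        "csf": np.clip(cov[2] - cov[3], 0.0, 1.0) + vent_cov,
    }

    rng = np.random.default_rng(spec.seed)
    sigma_vox = spec.pv_sigma / sp
    maps = {}
    for name, cover in regions.items():
        data = cover.astype(np.float32)
        if sigma_vox > 0:
            data = ndimage.gaussian_filter(data, sigma=sigma_vox)
        maps[name] = data.astype(np.float64)
    if spec.noise_sd > 0:
        for name in maps:
            maps[name] = np.clip(
                maps[name] + rng.normal(0.0, spec.noise_sd, size=grid.shape), 0.0, 1.0
            )
    total = sum(maps.values())
    over = total > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / np.maximum(total, 1.0), 1.0)
        for name in maps:
            maps[name] = maps[name] * scale

    ts = TissueSet(
        **{
            name: ScalarVolume(grid=grid, values=maps[name], is_probability=True)
            for name in ("gm", "wm", "csf", "bone", "soft")
        }
    )
    mask = BinaryMask(
        grid=grid,
        values=ndimage.binary_dilation(vent_cov > 0, structure=_ball_footprint(2.0 / sp)),
    )
    return ts, mask, truth


# ---------------------------------------------------------------------------
# Metric-level cohort simulation
# ---------------------------------------------------------------------------

#: Canonical metric column order used by statistics and classification.
METRIC_COLUMNS = (
    "head_circumference_cm",
    "icv_ml",
    "brain_ml",
    "gm_ml",
    "wm_ml",
    "csf_total_ml",
    "csf_subarachnoid_ml",
    "csf_ventricular_ml",
    "ventricular_sa_cm2",
    "ventricular_ai",
    "total_csf_ai",
)

#: Per-metric (mean, SD) for the control (HC) and autism (ASD) groups of the
#: adult-male reference cohort; these are the simulator defaults.
TABLE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "head_circumference_cm": {"HC": (57.4, 1.8), "ASD": (58.3, 2.1)},
    "icv_ml": {"HC": (1579.0, 119.0), "ASD": (1600.0, 152.0)},
    "brain_ml": {"HC": (1286.0, 102.0), "ASD": (1300.0, 133.0)},
    "gm_ml": {"HC": (794.0, 71.0), "ASD": (806.0, 91.0)},
    "wm_ml": {"HC": (491.0, 48.0), "ASD": (493.0, 58.0)},
    "csf_total_ml": {"HC": (294.0, 72.0), "ASD": (301.0, 94.0)},
    "csf_subarachnoid_ml": {"HC": (276.0, 69.0), "ASD": (279.0, 90.0)},
    "csf_ventricular_ml": {"HC": (18.0, 6.0), "ASD": (21.0, 10.0)},
    "ventricular_sa_cm2": {"HC": (104.0, 17.0), "ASD": (113.0, 24.0)},
    "ventricular_ai": {"HC": (0.029, 0.020), "ASD": (-0.033, 0.024)},
    "total_csf_ai": {"HC": (0.012, 0.0049), "ASD": (0.013, 0.0050)},
}

#: Group age distributions (mean, SD) in years, truncated at 20 (adults only).
AGE_PARAMS = {"HC": (27.6, 6.9), "ASD": (28.6, 8.7)}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the metric-level cohort simulator.

    Defaults reproduce the reference study conditions: 120 adult males with
    ASD and 136 controls, group-specific metric means/SDs, ages truncated at
    20 years.  ``correlation`` (11x11, `METRIC_COLUMNS` order) imposes a
    between-metric correlation structure shared by both groups; the default is
    independence.
    """

    n_asd: int = 120
    n_hc: int = 136
    params: dict = field(default_factory=lambda: {k: dict(v) for k, v in TABLE_PARAMS.items()})
    age_params: dict = field(default_factory=lambda: dict(AGE_PARAMS))
    correlation: np.ndarray | None = None
    min_age: float = 20.0
    seed: int = 0

    @staticmethod
    def hc_icv_correlation(r: float = math.sqrt(0.427)) -> np.ndarray:
        """Identity correlation with head-circumference/ICV correlation ``r``.

        The default ``r`` is the square root of the variance fraction of head
        circumference that ICV explains in the reference cohort (~0.427).
        """
        corr = np.eye(len(METRIC_COLUMNS))
        i = METRIC_COLUMNS.index("head_circumference_cm")
        j = METRIC_COLUMNS.index("icv_ml")
        corr[i, j] = corr[j, i] = r
        return corr


def simulate_metric_cohort(cs: CohortSpec) -> pd.DataFrame:
    """Draw a metric-level cohort table: one row per subject.

    Metrics are drawn per group from a multivariate normal with the group's
    means/SDs and the shared correlation matrix; ages from a normal truncated
    below at ``min_age``.  Deterministic given ``seed``.
    """
    metrics = list(METRIC_COLUMNS)
    k = len(metrics)
    if cs.correlation is None:
        corr = np.eye(k)
    else:
        corr = np.asarray(cs.correlation, dtype=float)
        if corr.shape != (k, k):
            raise PhantomSpecError(f"correlation must be {k}x{k}")
        if np.min(np.linalg.eigvalsh((corr + corr.T) / 2.0)) < -1e-10:
            raise PhantomSpecError("correlation matrix is not positive semidefinite")
    for name in metrics:
        for grp in ("HC", "ASD"):
            if cs.params[name][grp][1] < 0:
                raise PhantomSpecError(f"negative SD for {name}/{grp}")

    rng = np.random.default_rng(cs.seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    rows = []
    for grp, n in (("ASD", cs.n_asd), ("HC", cs.n_hc)):
        mu = np.array([cs.params[m][grp][0] for m in metrics])
        sd = np.array([cs.params[m][grp][1] for m in metrics])
        z = rng.standard_normal((n, k)) @ chol.T
        values = mu + z * sd
        age_mu, age_sd = cs.age_params[grp]
        ages = age_mu + age_sd * rng.standard_normal(n)
        # truncate below at min_age by redrawing (vectorized rejection)
        for _ in range(100):
            bad = ages < cs.min_age
            if not bad.any():
                break
            ages[bad] = age_mu + age_sd * rng.standard_normal(int(bad.sum()))
        ages = np.maximum(ages, cs.min_age)
        for i in range(n):
            rows.append(
                {"subject_id": f"{grp.lower()}_{i:04d}", "group": grp, "age": ages[i]}
                | {m: values[i, j] for j, m in enumerate(metrics)}
            )
    return pd.DataFrame(rows)
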