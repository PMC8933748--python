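# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `headmorph`. Everything stated here is computed by the
package's tests or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Coordinate conventions

All measurement code operates in a fixed RAS-like world frame: +x = subject
right, +y = anterior, +z = superior, units mm. `volume_io.canonicalize`
brings any axis-aligned NIfTI volume into this frame by axis permutation and
flips (lossless) and resamples anisotropic grids trilinearly to 1 mm
isotropic (values outside the field of view are zero). Oblique affines are
rejected rather than silently resampled: rigid registration to a standard
alignment is an upstream responsibility, and laterality metrics are only
meaningful after it. Resampling of anisotropic inputs is our policy choice;
nominally isotropic research data usually makes it a no-op.

Probability maps are clipped to [0, 1] at load; a warning fires if more than
0.1% of voxels were out of range, since that typically means the file is not
a probability map. A tissue set is valid when all five maps share one grid
and the per-voxel probability sum stays below 1.05; validation reports, it
never raises, so a pipeline can log and continue.

## Planimetry

The head probability is the per-voxel sum of the five tissue probabilities
(clipped at 1). The measurement plane is the axial slice whose world z is
nearest 0 mm — through the mid-forehead and the most prominent occiput on a
standard-aligned head — with exact ties broken toward inferior for
determinism. Smoothing before binarization uses a Gaussian kernel specified
by FWHM (default 4 mm per axis, the neuroimaging convention for a "4 × 4 × 4
mm³ kernel"); binarization is strictly `> t` with t = 0.5, so a constant 0.5
field is background. Both are configurable.

**Perimeter estimator.** The largest 8-connected foreground component is
kept (neck slices and artifacts must not contribute), interior holes are
filled (the head is simply connected at this level), and the outer boundary
is traced by Moore-neighbor following with Jacob's stopping criterion. The
perimeter is the chain-code length (straight step = pixel spacing, diagonal
step = √2 × spacing) multiplied by a global 0.95 digitization-bias
correction: (1, √2)-weighted chain codes overestimate smooth contours by
~5.5% on average over boundary orientations, so the correction removes the
expected bias rather than matching any particular software dialect. Against
continuous circles and ellipses rasterized at 1 mm the estimator is accurate
to better than 2%, and the error is non-increasing as pixel spacing shrinks
(tested). Single-pixel regions are flagged degenerate and get a zero-length
perimeter.

**Axes.** Primary length and width are the major/minor axis lengths of the
ellipse with the same normalized second central moments as the filled region
(not Feret diameters): an explicit, rotation-robust definition. The cephalic
index uses half-open class intervals, assigning boundary values upward
(CI = 80 is brachycephalic when computed from exact axes).

**2D areas.** Head (five tissues), ICV (GM+WM+CSF), and brain (GM+WM) planes
are smoothed and binarized exactly like the head mask; area = pixel count ×
pixel area. A probabilistic option (unsmoothed probability sum × pixel area)
is exposed because either reading of "area in the plane" is defensible; the
binarized variant is the default.

## Volumetry

Compartment volumes are probabilistic sums (Σ p · voxel volume), so the
additivity identities — total CSF = ventricular + subarachnoid, ICV = brain +
total CSF, brain = GM + WM — hold to machine precision by construction, on
any input. The ventricular/subarachnoid split gates CSF probabilities with
the binary ventricle mask (probability × indicator, no re-thresholding),
preserving probabilistic volumetry inside the mask. Any standard-space
binary ventricle mask is accepted; phantoms carry their own truth mask.

Hemispheric splits use world x = 0; a voxel whose center lies within half a
voxel of the midline contributes half to each side, which makes the
asymmetry index exactly zero for grid-symmetric inputs. AI =
(right − left)/(right + left), undefined (NaN) for empty fields; the sign
flips under mirror reflection (property-tested).

Ventricular surface area runs marching cubes on the masked CSF *probability*
field at the 0.5 isosurface — not on a binarized mask — so the surface is
placed at sub-voxel positions and triangle areas converge to the continuous
surface. The iso level is nudged by 1e-6 because fields with plateaus exactly
at the level otherwise produce degenerate, non-watertight triangulations.
The field is cropped to the mask bounding box (2-voxel pad) purely for speed.

## The phantom generator

The phantom is a nest of concentric ellipsoids — scalp/soft tissue, skull,
subarachnoid CSF, grey matter, white matter filling the remainder — plus two
ellipsoidal lateral ventricles (CSF) embedded in the white matter at ±offset
from the midline. `right_scale` multiplies the right ventricle's semi-axes
to create controlled asymmetry. Defaults (outer semi-axes 80 × 95 × 70 mm,
shells 5/6/3/4 mm, ventricles (8, 25, 10) mm at ±15 mm offset) give a head
circumference of ~55 cm, an ICV of ~1.4 l, and ~17 ml of ventricular CSF —
adult-male-plausible magnitudes. The default ventricle center sits at
z = +15 mm so the measurement plane at z = 0 does not cut through it; specs
that violate this make the analytic 2D brain/ICV area values invalid (the 3D
metrics remain exact).

Rasterization is antialiased: each ellipsoid is converted to a per-voxel
inside *fraction* via a linear ramp in the signed distance (linearized from
the quadratic form), keeping rasterized masses within ~0.1% of analytic
volumes at 1 mm even for small, eccentric ventricles — voxel-center counting
errs by ~1% there, which would consume the whole volumetric error budget.
Partial-volume structure is then emulated by Gaussian smoothing of the
region fractions (`pv_sigma`, default 1 mm); by linearity the five maps
still sum to ≤ 1. Optional i.i.d. Gaussian probability noise (`noise_sd`) is
added per tissue, clipped to [0, 1], and voxels pushed above unit total are
renormalized. The ventricle truth mask is the set of voxels touching either
ventricle, dilated by a 2 mm ball — deliberately generous, as standard-space
ventricle masks are; the split must tolerate masks larger than the structure.

Analytic truth uses exact ellipsoid volumes, Ramanujan's second
approximation for the z = 0 ellipse perimeter (error ≪ 0.01% at head-like
eccentricities; cross-checked against the complete elliptic integral), and
Thomsen's approximation (p = 1.6075, max error ~1.06%) for ventricular
surface area, summed over the two disjoint ventricles. The truth cephalic
index is 100 · min/max of the plane semi-axes, consistent with the
measurement-side convention width ≤ length for any axis ordering.

What the phantom does *not* emulate: cortical folding, skull sutures and
apertures, MR intensity artifacts, segmentation errors correlated with
anatomy, or non-ellipsoidal ventricle shape. Passing phantom tests therefore
demonstrates the correctness of the measurement chain, not the accuracy of
any upstream segmentation.

**Metric-level cohort simulator.** Draws per-subject metric vectors from
group-specific multivariate normals. Defaults are the reference adult-male
study conditions: 120 ASD vs 136 control subjects (the group sizes follow
the sample description; a table header elsewhere in the source swaps the
two ns), per-metric means/SDs as published (head circumference 58.3 ± 2.1 vs
57.4 ± 1.8 cm, ventricular CSF 21 ± 10 vs 18 ± 6 ml, …), ages normal
truncated at 20 years. Metrics are independent by default; a helper imposes
the head-circumference/ICV correlation of √0.427 implied by the reference
variance decomposition, for probing stepwise-regression behavior.

## Statistics

- **t-tests** are pooled-variance (Student), matching df = n₁+n₂−2
  reporting conventions; Welch is deliberately not the default here.
- **χ²** is Pearson without continuity correction; zero-margin rows/columns
  are dropped with a warning.
- **ANCOVA** fits outcome ~ 1 + group + covariates by least squares; the
  group F is the nested-model comparison ((SSE_r − SSE_f)/1)/MSE_f on
  (1, n − p) df. Adjusted group means are predictions at the grand covariate
  mean; an age-adjusted Cohen's d (adjusted mean difference / root MSE) is
  reported alongside the raw pooled-SD d, because a covariate-adjusted d is
  not derivable from group summary statistics alone. Verified numerically
  against statsmodels' type-III ANOVA in the test suite.
- **MANCOVA** computes Wilks' Λ = det(E)/det(E+H) from residual SSCP
  matrices of the full and reduced multivariate fits. The group hypothesis
  has one df, so Rao's transformation gives an *exact* F on
  (p, n − r − p + 1) df; Pillai's trace is reported as well (equivalent for
  1-df hypotheses). Singular E raises with a suggestion to reduce the
  outcome list. Cross-checked against statsmodels MANOVA.
- **Stepwise regression** uses forward entry by smallest partial-F p-value
  (enter if p < .05) and backward removal (remove if p > .10), the classic
  defaults of the era's statistics packages, iterated to stability; both
  thresholds are configurable. A saturated base model (R² = 1) blocks
  further entries. The per-candidate false-entry rate under the null sits
  near p_enter (slightly above, since the forward step takes the minimum of
  k p-values — measured ~0.05 at n = 200, k = 5).
- **Power / sample size** uses the noncentral t distribution: power at
  per-group n is P(|T| > t₀.₉₇₅,₂ₙ₋₂) for T ~ nct(2n−2, d√(n/2)); the
  required n is found by bisection and is inverse-consistent (power(n) ≥
  target > power(n−1), and Monte-Carlo simulation at the returned n matches).
  d = 0.4, α = .05, power .80 yields 100 per group.
- **Cronbach's α** is the standard k/(k−1)·(1 − Σ column var / var of row
  sums). Measurement reliability is demonstrated on phantom re-measurement
  under re-seeded noise (the internal-dataset reliability figure of the
  reference workflow is not reproducible without its private data).
- No multiple-testing correction is applied anywhere, matching the analysis
  this package mirrors; p-values are raw and callers can correct downstream.

## Classification

Features are min–max scaled to [0, 1] **on the training rows only** by
default; test rows are transformed with the training parameters and may fall
outside [0, 1]. A pooled-sample scaling option exists for fidelity with
workflows that rescale before splitting; the leakage-free variant is the
default on correctness grounds. The stratified split allocates
ceil((1−f)·n) test subjects across classes by largest remainder —
120 + 136 subjects at f = 0.8 give exactly 204 train / 52 test. The SVM
minimizes ½‖w‖² + C Σ max(0, 1 − yᵢ(w·xᵢ+b))² (squared hinge, l2, C = 1 by
default), solved in the primal via liblinear (deterministic for fixed data;
duplicating the training set is equivalent to doubling C, which is asserted
in the tests). The clinical (ASD) group is the positive class, so
sensitivity is clinical-case detection. Weight contributions are
100·|wᵢ|/Σ|wⱼ| and sum to 100 whenever any weight is nonzero. No point
reproduction of any published accuracy is attempted: that number depends on
one unknown split of data this package does not ship.

## Problem sizes and tolerances used in validation

The acceptance battery uses: the full-scale noiseless phantom (outer
semi-axes 100 × 80 × 70 mm, 1 mm grid, ~5.4M voxels) for geometry recovery —
tolerances 2% on circumference, 1% on CI and all compartment volumes, 3% on
ventricular surface area, ±0.01 on the symmetric AI; 1000-rep null
simulations at n = 100/group for type-I calibration (band 0.035–0.065 at
α = .05); 2000-rep simulations for power inverse-consistency; 500 reps for
stepwise false-entry; six scaled phantoms × two noise seeds
(noise_sd = 0.02) for reliability, requiring α ≥ 0.8. Unit tests run on a
scaled-down phantom (outer 40 × 50 × 35 mm) whose ventricles are chosen
large enough relative to the partial-volume smoothing that the same
tolerance bands apply.

## Known limitations

- The perimeter definition is planimetric (region boundary in one plane),
  not a 3D tape path over the scalp between anatomical landmarks; the two
  differ on heads with unusual occipital profiles.
- Chain-code bias correction is calibrated for smooth convex-ish contours;
  heavily crenellated masks (pathological segmentations) will read long.
- The MANCOVA assumes a common within-group covariance and complete cases.
- `LinearSVC` regularizes the intercept weakly (intercept_scaling = 10); for
  the scaled features used here the effect is negligible but it is not a
  mathematically intercept-free formulation.
- Phantom cohort metrics are drawn independently unless a correlation matrix
  is supplied; real morphometric batteries are strongly correlated, so
  simulated stepwise/SVM behavior under the default is conservative.
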