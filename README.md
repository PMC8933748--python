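# headmorph

Automated, user-independent head circumference and cerebral morphometry from
structural MRI tissue-probability maps, with cohort statistics and linear-SVM
phenotype stratification — validated end-to-end on synthetic head phantoms with
analytic ground truth.

## Who this is for

Neuroimaging groups who want to measure head circumference and a battery of
cranial/CSF metrics retrospectively on large T1 datasets (for example when
studying macrocephaly-linked phenotypes such as autism spectrum disorder in
adults), without manual tape measurements. The package consumes the five
tissue probability maps a standard unified-segmentation pipeline produces
(grey matter, white matter, CSF, bone, soft tissue) on a 1 mm standard-aligned
grid, plus a standard-space binary lateral-ventricle mask.

## What it computes

**Planimetry (2D, world z = 0 plane).** The five tissue maps are summed into a
head probability, smoothed with a 4 mm FWHM Gaussian, binarized at t > 0.5,
and the axial slice through mid-forehead and occiput (z = 0) is measured:

- head circumference = perimeter of the head region (bias-corrected
  chain-code length of the traced boundary), in cm;
- primary length/width = major/minor axes of the moment-equivalent ellipse;
- cephalic index CI = 100 · width / length, with the conventional
  dolicho/meso/brachy/hyperbrachycephalic classes on [70,75), [75,80),
  [80,85), [85,90);
- 2D areas of head, intracranial space (GM+WM+CSF), and brain (GM+WM).

**Volumetry (3D, probabilistic).** Each compartment volume is the sum of
voxel probabilities × voxel volume: ICV = GM+WM+CSF, brain = GM+WM;
ventricular CSF = Σ CSF·mask, subarachnoid = total − ventricular;
hemispheric asymmetry AI = (right − left)/(right + left) about the world
midline for ventricular and total CSF; ventricular surface area from a
marching-cubes triangulation of the masked CSF probability field at the 0.5
isosurface.

**Cohort statistics.** Pooled-variance t-tests and χ² for demographics; the
primary ANCOVA (group effect on head circumference adjusting for age) with
Cohen's d; a MANCOVA over the secondary metrics (Wilks' Λ, Rao's exact F for
the 1-df group hypothesis) with per-outcome post hocs; ANCOVAs for absolute
hemispheric differences with the corresponding volume as extra covariate;
forward/backward stepwise regression of head circumference on the brain
metrics; a noncentral-t power/sample-size calculator; Cronbach's α for
test–retest reliability.

**Classification.** Min–max scaled 11-feature battery, stratified 80/20
split, linear SVM (squared hinge, l2 penalty, C = 1), accuracy / sensitivity /
specificity with the clinical group as positive class, and percentual feature
weight contributions.

**Phantoms.** Because real cohort data cannot ship with the package, a
phantom module generates five-tissue heads as nested ellipsoids (scalp, skull,
subarachnoid CSF, grey matter, white matter) with two ellipsoidal lateral
ventricles, partial-volume smoothing and optional probability noise. Every
metric above has a closed form for this geometry, which is the test oracle.
A metric-level cohort simulator draws subject tables from group-specific
multivariate normals (defaults = the reference adult-male ASD/control cohort:
120 vs 136 subjects, head circumference 58.3 ± 2.1 vs 57.4 ± 1.8 cm, …) so the
statistics and classification stages can be exercised at scale.

## Worked example

```python
from headmorph.phantom import PhantomSpec, generate_phantom
from headmorph.pipeline import RunConfig, measure_subject

spec = PhantomSpec(outer_semi_axes=(100.0, 80.0, 70.0))  # mm
tissues, ventricle_mask, truth = generate_phantom(spec)
row = measure_subject(tissues, ventricle_mask, RunConfig())
print(f"circumference {row['head_circumference_cm']:.1f} cm "
      f"(analytic {truth.circumference_cm:.1f} cm)")
print(f"CI {row['cephalic_index']:.1f} ({row['shape_class']})")
print(f"ICV {row['icv_ml']:.0f} ml, ventricular CSF {row['csf_ventricular_ml']:.1f} ml, "
      f"ventricular SA {row['ventricular_sa_cm2']:.1f} cm2, AI {row['ventricular_ai']:.3f}")
```

prints

```
circumference 56.3 cm (analytic 56.7 cm)
CI 80.0 (mesocephalic)
ICV 1518 ml, ventricular CSF 16.8 ml, ventricular SA 45.8 cm2, AI 0.000
```

i.e. the pipeline recovers the analytic circumference within 1%, the cephalic
index to 0.05% (this spec sits exactly on the meso/brachycephalic boundary,
so the unrounded measured CI of 79.97 classifies as mesocephalic), all
compartment volumes within 0.1%, and reports exact left–right symmetry for
the symmetric spec.

The same measurement runs from the shell on real data via a manifest CSV
(`subject_id` plus the five map paths):

```bash
headmorph measure --manifest subjects.csv --mask ventricles.nii.gz --out metrics.csv
headmorph study --metrics metrics.csv --out report.json --seed 1
```

`report.json` contains the demographics tests, the primary ANCOVA with d and
the required sample size at that effect, the MANCOVA with post hocs, the
stepwise path with cumulative R², and the SVM block (accuracy, sensitivity,
specificity, weight contributions).

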