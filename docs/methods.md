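# Methods

This note documents the models, parameters and numerical choices behind
`dosemimic`, in the spirit of a software methods appendix.

## Scope and assumptions

The package implements the *planning-support* half of a dose-mimicking
workflow: dose prediction, block generation, and evaluation.  It does
not optimize deliverable plans — feeding the exported block into a
treatment planning system, beam modelling, and delivery-time analysis
are outside its scope.  All volumes are assumed axial-slice DICOM LPS
geometries; dose grids are resampled onto the CT grid at load so every
downstream computation uses one grid per patient.

## Data model

`GridGeometry` carries origin (mm, voxel-center convention), per-axis
spacing, shape and orthonormal direction cosines; arrays are stored in
`(z, y, x)` index order.  Masks are exact voxelizations: structure
volume is `count(true) × voxel volume`, with no partial-volume model.
Contours rasterize by even-odd (XOR) polygon filling per axial slice at
voxel centers, so nested contours produce holes; contour extraction
runs marching squares at the 0.5 level.  DICOM round-trips are exact up
to the RTDOSE scaling quantization (`DoseGridScaling` is chosen as
`max dose / (2^31 - 1)`, making the quantization error ≪ 1 mGy).

## Phantom cohort generator

The generator emulates a cohort of left-sided breast/chest-wall
radiotherapy patients as smooth deformations of one template on a
96×96×48 grid at 3×3×5 mm (in-plane dose-grid resolution 3 mm, slice
thickness 5 mm — typical planning-CT values).

Template anatomy (all analytic solids, intersected with the body and
made mutually disjoint): an elliptic-cylinder body (260×190 mm axes),
two ellipsoidal lungs at −700 HU, a spherical-ish heart shifted toward
the patient's left, a breast mound + chest-wall slab + parasternal
(internal-mammary) strip forming `PTV_Breast` (~580 cc, within the
300–900 cc range of clinical cohorts), a supraclavicular target
`PTV_SCF` (~100 cc), contralateral breast, esophagus and spinal cord.
The medial edge of the target chain reaches the midline, as in
locally-advanced disease with internal-mammary irradiation; this places
the contralateral lung a few cm from the target, which is what makes
the helical bath reach it appreciably.  Soft tissue is 20 HU, air
−1000 HU, and the HU map is smoothed with a 1-voxel Gaussian so the
phantom has soft edges and a usable intensity gradient.

Inter-patient variation is a random B-spline-style displacement field:
i.i.d. normal coefficients with SD = `deform_amplitude_mm` (default
5 mm) on a 50 mm control grid, cubic-upsampled, with magnitude clamped
at `2 × amplitude` so the fields remain invertible in practice.  Case
CTs warp linearly, masks by nearest neighbour, and each case's dose is
synthesized *in its deformed geometry*.  Cohort generation is a pure
function of the `PhantomSpec` (seed included).

Two analytic dose styles emulate the delivery-technique contrast the
workflow exploits:

* **tangential** — prescription inside the targets; inside two oblique
  ±45° corridor slabs through the breast-target centroid (restricted to
  the ipsilateral-anterior chest), dose decays laterally as
  `exp(−d_perp / 12 mm)`; zero elsewhere.  This reproduces the tight
  lateral falloff and near-zero contralateral dose of tangential arcs.
* **helical** — prescription inside the targets plus a bath
  `6 Gy × exp(−d(x, PTV) / 40 mm)` everywhere in the body, with
  `d` the Euclidean distance transform to the target union.

Both are clipped to `[0, 1.1 × prescription]`.  With the default
parameters the template's contralateral-lung mean dose is ≈2.3 Gy
(helical) vs ≈0.0 Gy (tangential) — the same qualitative contrast
reported for clinical helical-vs-tangential cohorts (≈3.1 vs
≈0.8 Gy) — and every case's helical 2-Gy isodose volume exceeds its
tangential one, which is the premise of the whole workflow.

What the phantoms do **not** model: realistic CT texture and noise,
breathing motion, bone/couch, beam transport (the corridors and bath
are geometric stand-ins), or inter-patient topology changes.  Passing
tests on phantoms therefore demonstrate the *pipeline's* correctness
and self-consistency, not clinical prediction accuracy.

## Registration

Two stages, configured via `RegistrationConfig`:

1. **Affine**: multiresolution (3 levels, shrink factors 4, 4, 2;
   smoothing sigmas 2, 1, 0 voxels), mean-squared-error metric,
   regular-step gradient descent, 20 iterations per level, scales from
   physical shift, geometry-centered initialization.
2. **B-spline**: uniform 50 mm isotropic control-point grid, seeded by
   the affine result, same pyramid, LBFGS-B with 30 iterations per
   level.  The iteration budget is interpreted *per level*
   (configurable in spirit via the config's iteration fields).

The similarity metric defaults to intensity MSE — the natural choice
for same-modality CT-to-CT registration; correlation is available via
config.  The metric samples 10 % of voxels with a fixed seed, so a
given config is bit-reproducible.  The total transform (affine ∘
B-spline refinement) is exported as one displacement field on the
fixed grid, mapping fixed to moving coordinates (pull-back):
`out(x) = in(x + u(x))`.

Field inversion uses fixed-point iteration
`v_{k+1}(y) = −u(y + v_k(y))` (≤ 20 iterations, tolerance 0.1 mm mean
residual); non-convergence warns but returns the best iterate.  On the
default phantoms, self-registration displacement is ≈0 mm, a 6 mm
translation is recovered to ≪1 mm, and inverse-consistency residuals
are <0.1 mm over the body.

## Similarity weighting and prediction

All similarity comparisons happen in the reference frame (the only
frame in which all atlas members coexist).  The slice-wise SSIM uses
the standard Gaussian-window form with constants `c1=(0.01 L)²`,
`c2=(0.03 L)²`; the dynamic range `L` is fixed from a CT window of
−1000..1000 HU rather than the per-image range, so air-only slices
cannot inflate similarity, and the slice set is restricted to slices
intersecting the body.  Scores are clamped to ≥1e-6 before the
sharpening power `p` (default 1) and normalization, guaranteeing
nonnegative convex weights; as `p → ∞` the prediction converges to the
most similar member's warped dose.  The reference participates in the
sum as a member with identity warp.  The prediction is therefore a
convex combination of warped member doses: voxelwise bounded by their
range and nonnegative by construction.

## Block generation

`body AND NOT (dose ≥ 2 Gy)` (the threshold is inclusive, matching the
`V_x ≥ x Gy` convention), then morphological closing (5 mm spherical
element) followed by opening (2 mm) for geometric continuity.
Morphology runs on an edge-replicate-padded array so structures
touching the grid border are not artificially eroded.  The result is
clipped to the body and, by default, re-trimmed against the isodose so
the final block can never overlap the predicted 2-Gy region.  Block
constraints (`Dmax < 2 Gy`, `V1 < 50 %`) are checked with strict
inequalities, matching the planning-constraint notation.  The
smoothing radii are declared defaults, not values reverse-engineered
from any TPS.

## Dosimetry

All metrics are exact voxel counts; `D_x%` interpolates linearly along
the descending sorted dose distribution (defined as the largest dose
received by at least x % of the volume).  The DVH uses 0.01 Gy bins by
default but every `V`/`D` query bypasses binning and counts voxels
directly.  CI defaults to Paddick at the 95 % isodose,
`(TV_PIV)² / (TV·PIV)`, with a simple coverage ratio as the
configurable alternative; HI is ICRU-83 `(D2% − D98%)/D50%`.  Both
definitions are recorded in every emitted metric table, because the
literature's CI/HI conventions vary and reported values are not
comparable across definitions.  Integral dose is mean dose × volume at
unit density, in Gy·L.

## Statistics

Fisher's exact two-sided p is computed in-repo by hypergeometric
enumeration with the point-probability rule (sum of all tables at
fixed margins whose probability does not exceed the observed table's,
with a 1+1e-7 relative guard against floating-point ties); this is the
convention that reproduces the published baseline-table p-values
(0.634, 0.601, 1.000) exactly, where e.g. a doubling rule would not.
The Holm–Bonferroni step-down correction is likewise implemented
directly (reject while `p_(k) ≤ α/(m−k+1)`; adjusted p is the running
maximum of `(m−k+1)·p_(k)` capped at 1) and verified against a literal
enumeration oracle.  Wilcoxon signed-rank p-values are exact for
n ≤ 25 via the sign-flip distribution computed by dynamic programming
over doubled average ranks — valid in the presence of tied
|differences|, where textbook exact tables are not — and normal
approximation beyond.  Mann–Whitney U and Friedman delegate to
scipy.stats (exact Mann–Whitney for tie-free samples of ≤25).
Comparison tables declare their contrasts up front; paired families
are gated by Friedman and corrected with Holm within each metric.

## Leave-one-out validation

Each fold removes one case, builds the atlas from the rest (reference:
the pinned id if still present, else the first remaining case in id
order), predicts the held-out dose, and scores DSC of the 2-Gy
isodose plus mean absolute dose error over the body.  Registration
results are memoized across folds keyed by (fixed, moving) case ids —
registration is deterministic, so the cache only removes repeated
identical computations (18 distinct registrations instead of 90 for a
10-case cohort).

Default study conditions for the synthetic validation: 10 cases, seed
42, 5 mm deformation amplitude, helical dose style, 96×96×48 grid.
Registration-heavy unit tests run on a coarse 48×48×24 grid with the
same physical extent, which keeps the full suite within a desktop-scale
run while exercising identical code paths.

## Known limitations

* The analytic dose styles carry no scatter, no beam penumbra model in
  the longitudinal direction, and a hard lateral cutoff on the
  tangential corridors.
* SSIM weighting is global per member; no local (per-region) weighting.
* The fixed-point field inverse assumes moderate, smooth displacements
  (guaranteed for the phantom generator's clamped fields, not for
  arbitrary clinical registrations).
* Prediction blurs steep dose gradients near target edges — inherent
  to weighted-fusion approaches; the workflow only relies on the shape
  of the flat low-dose region.
* Non-axis-aligned DICOM orientations are read into the data model but
  not supported by the rasterizer/writer.
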