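# dosemimic

Atlas-based low-dose prediction and personalized avoidance-block
generation for helical radiotherapy planning of left-sided breast
cancer.

## The problem

Helical (rotational) delivery achieves excellent target conformity but
spreads a characteristic **low-dose bath** (~1–5 Gy) over large volumes
of the heart, both lungs and the contralateral breast — a concern for
long-term cardiac toxicity and secondary malignancy, especially in
younger patients.  Tangential partial-arc VMAT (t-VMAT), by contrast,
confines dose to two oblique corridors through the breast and leaves
the contralateral side essentially unirradiated.

`dosemimic` transfers the low-dose sparing of a library of tangential
plans onto helical delivery.  For a new patient it:

1. **predicts** a patient-specific 3D "tangential-like" dose
   distribution by deformable-image-registration (DIR) based fusion of
   an atlas of reference plans;
2. **derives** a *complete block* — an avoidance structure through
   which no beamlet may pass — as the Boolean subtraction
   `body − (predicted dose ≥ 2 Gy)`, morphologically smoothed;
3. **evaluates** the result with standard dose-volume metrics (DVH,
   V_x, D_x%, conformity and homogeneity indices, integral dose, Dice
   coefficients) and a nonparametric statistics harness.

## The model

Given atlas cases with CT images $I_1,\dots,I_n$ and doses
$D_1,\dots,D_n$, all deformably registered into the frame of a
reference case, and a test patient with CT $I_t$:

* register $I_t$ to the reference with a multiresolution affine stage
  (20 iterations, 3 levels, downsampling 4×4×2) followed by a B-spline
  stage (30 iterations per level, 50 mm isotropic control-point grid),
  yielding a displacement field $F$ and its fixed-point inverse
  $F^{-1}$;
* score each atlas member by mean slice-wise structural similarity
  $s_i = \mathrm{SSIM}(I_t \circ F,\, I_i)$ over body slices;
* form convex weights $w_i = s_i^p / \sum_j s_j^p$ (default $p=1$);
* predict $\hat D_t = \sum_i w_i \,(D_i \circ F^{-1})$.

The predicted 2-Gy isodose is subtracted from the body contour,
smoothed by morphological closing (5 mm) and opening (2 mm), and the
result is exported as a `CompleteBlock` ROI in DICOM RTSTRUCT.  Block
quality is checked against the planning constraints
$D_\mathrm{max} < 2$ Gy and $V_1 < 50\%$.

Validation is leave-one-out cross-validation scored with the Dice
similarity coefficient of the 2-Gy isodose,
$\mathrm{DSC} = 2|A \cap B|/(|A|+|B|)$.

Since no clinical imaging can ship with the package, a seeded
**phantom generator** produces cohorts of thorax-like phantoms (body,
lungs, heart, breast + chest-wall + supraclavicular targets) that are
smooth random B-spline deformations of a common template, each carrying
one of two analytic dose styles: *tangential* (tight lateral falloff,
no contralateral dose) or *helical* (conformal target dose plus an
exponential low-dose bath).

## Worked example

```python
from dosemimic import (
    PhantomSpec, make_phantom_cohort, build_atlas, predict_dose,
    extract_isodose, make_complete_block, check_block_dose, dice,
)

spec = PhantomSpec(seed=3, dose_style="helical")
cohort = make_phantom_cohort(3, spec)

cache = {}
atlas = build_atlas(cohort.cases[:2], cohort.cases[0].id, reg_cache=cache)
pred = predict_dose(atlas, cohort.cases[2], reg_cache=cache)
print("weights:", pred.weights.weights)

iso = extract_isodose(pred.predicted_dose, 2.0)
true_iso = extract_isodose(cohort.cases[2].dose, 2.0)
print("DSC(2 Gy):", dice(iso, true_iso))

block = make_complete_block(cohort.cases[2].structures["Body"], iso)
print(check_block_dose(block, pred.predicted_dose))
```

Output:

```
weights: [0.50617085 0.49382915]
DSC(2 Gy): 0.907564069118871
{'applicable': True, 'dmax_gy': 1.9999944819141577,
 'v1_pct': 37.90072085799684, 'dmax_pass': True, 'v1_pass': True}
```

The two atlas members are near-equally similar to the test anatomy, so
they receive near-equal weights; the predicted 2-Gy isodose overlaps
the true one with Dice 0.91; and the resulting block — by construction
disjoint from the predicted 2-Gy region — meets both of its planning
constraints.

The same workflow is available from the shell:

```bash
dosemimic simulate-cohort --n 6 --seed 42 --style helical --out cohort/
dosemimic validate-loo --cases cohort/ --out loo.csv
dosemimic run-all --out run/ --seed 42   # full pipeline + manifest
```

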