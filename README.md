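# splintnav

A toolkit for **registration-free intra-operative navigation** in orbital and
craniofacial surgery, and for quantifying its accuracy.

Conventional surgical navigation needs an intra-operative *registration*: a
rigid transform `T_reg` linking physical patient space (where a tracked
pointer moves) to pre-operative image space. Registration is invasive
(bone-anchored fiducial screws), user-dependent (surface matching) or costs
radiation and time (intra-operative imaging). The registration-free idea:
design a dental splint that carries the navigation system's dynamic reference
frame (DRF) in a pose known *by design* relative to the planning image
(`T_SPL→IPS`). Composing with the planning-to-navigation image-space
transform derived from the CT's DICOM header (`T_IPS→BL`, an RAS/LPS flip
plus the Image Position Patient offset) gives

```
T_SPL→BL = T_IPS→BL ∘ T_SPL→IPS
```

— the DRF pose in navigation image space, established pre-operatively.
Seating the splint on the dentition then links patient and image space with
no registration procedure at all. Because current systems still insist on a
registration, accuracy assessment uses a recalculation: coordinates `c`
acquired under an arbitrary pre-registration `T_reg` are pulled back to the
DRF frame (`c′ = T_reg⁻¹ c`) and pushed into image space
(`c″ = T_SPL→BL c′`); the result is provably independent of `T_reg`. The
target registration error (TRE) is `‖c″ − l‖` against the true landmark `l`.

The package provides:

* `splintnav.geometry` — frame-tagged 4×4 rigid/affine transform algebra,
  DICOM voxel→patient mapping, RAS/LPS conventions. Chains whose frames do
  not link raise before any numeric work.
* `splintnav.registration` — baseline methods: closed-form fiducial least
  squares (SVD with determinant correction, never a reflection) and
  point-to-surface ICP with exact closest points on mesh triangles; plus an
  independent numerical minimizer used as a cross-check.
* `splintnav.regfree` — the splint-DRF chain and the recalculation pipeline.
* `splintnav.simulator` — a synthetic cadaver-head phantom (5 near-coplanar
  maxillary fiducials, 14 cranial targets at named landmarks, splint-borne
  DRF, ellipsoidal skin surface) and a Monte-Carlo generator for the full
  factorial study (2 tracking techniques × registration methods × 2
  observers × 5 repetitions × 5 cadavers × 14 targets), with a first-order
  analytic TRE prediction as oracle.
* `splintnav.analysis` — the accuracy model: TRE covariates, the √TRE linear
  mixed model (statsmodels-style `SqrtTreModel` / `SqrtTreResults`),
  per-group intercept/slope lines, >2 mm proportions and distribution
  summaries.
* `splintnav.cli` / `splintnav.io` — file formats (landmark CSV, transform
  JSON, STL, DICOM header-only reads) and a thin `splintnav` command line.

## Worked example

Simulate the full factorial study with the default noise model, attach
covariates against each phantom's own geometry, and fit the √TRE mixed model:

```python
from splintnav.simulator import StudyDesign, NoiseModel, simulate_study, make_phantom
from splintnav.analysis import covariates_from_phantoms, fit_lmm, proportion_above

design = StudyDesign.reference()          # 5 arms x 700 records, 4 missing
study  = simulate_study(design, 17, NoiseModel(seed=17))
phantoms = [make_phantom(17 + 1000 * c) for c in range(design.n_cadavers)]
covs   = covariates_from_phantoms(study, phantoms)
print(fit_lmm(covs).summary())
print(proportion_above(covs, 2.0))
```

which prints (abridged):

```
sqrt(TRE) linear mixed model (REML, random effects: cadaver)
n obs: 3496   residual var: 0.06034   cadaver intercept var: 0.00058
converged: True

                               estimate      sd        t
intercept                        0.8281  0.0163  50.6915
distance                         0.0074  0.0002  31.2268
em                               0.0961  0.0174   5.5192
...

Derived group lines (intercept at infraorbital rim, slope per mm):
technique            method  intercept    slope  intercept_reported  slope_reported
  optical     bone_anchored   0.828104 0.007419                0.83          0.0074
  optical registration_free   0.776669 0.001594                0.78          0.0016
       em     bone_anchored   0.924194 0.008401                0.92          0.0084
       em     surface_based   0.535080 0.000627                0.54          0.0006
       em registration_free   0.754258 0.001652                0.75          0.0017
```

The intercept is the expected √TRE (√mm) at the infraorbital rim (the
distance covariate is centered there); each slope is the increase in √TRE
per millimetre of target distance from the splint centroid. Bone-anchored
arms show the steepest slopes — the near-coplanar maxillary fiducial patch
amplifies rotational registration error away from its centroid, exactly as
the first-order TRE theory (`predict_tre_point_based`) predicts. The
registration-free arms inherit only splint-seating and pointer error, so
their slopes are flat. Absolute levels depend on the configured noise
magnitudes, which are package defaults, not measured error budgets.

The same pipeline is scriptable:

```
splintnav simulate --seed 17 --out study.csv
splintnav register points --moving fid_patient.csv --fixed fid_image.csv --out Treg.json
splintnav regfree build --design design.json --dicom ct_series/ --out chain.json
splintnav regfree recalc --acquired c.csv --prereg Treg.json --chain chain.json \
                         --targets l.csv --out tre.csv
```

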