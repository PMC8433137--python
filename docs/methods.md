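# Methods

This note documents the models, conventions and numerical choices behind
`splintnav`, and what the synthetic study does and does not emulate.

## Coordinate frames and transform algebra

All geometry is expressed in named frames: `PATIENT` (tracker/physical
space, mm), `DRF` (the tracked reference body), `IPS_IMAGE` (planning image
space, RAS mm, origin at the first-voxel position), `BL_IMAGE` (navigation
image space, DICOM LPS patient mm) and `VOXEL` (0-based `(col, row, slice)`
indices). Transforms are homogeneous 4×4 matrices tagged with source and
destination frames; composing or applying anything whose frames do not link
raises a `FrameChainError` before numeric work, and no silent frame coercion
exists anywhere. Rigid matrices are validated on construction
(‖RᵀR − I‖∞ < 1e−9, |det R − 1| < 1e−9, exact last row); these tolerances
scale only through the single `set_strictness` knob. Rigid inverses are
formed analytically as (Rᵀ, −Rᵀt).

The voxel→patient map follows the DICOM plane equation
`P = IPP + col·Δcol·X + row·Δrow·Y + slice·Δslice·(X×Y)` with X, Y the IOP
column/row direction cosines (unit-norm and orthogonality checked at 1e−6).
Slice spacing should come from inter-slice position distances, not
SliceThickness, which is unreliable for geometry; the DICOM reader warns at
>1% spacing variation and fails in strict mode. The planning→navigation
image transform is constructed as `P_lps = F·p_ras + IPP` with
F = diag(−1,−1,1): the RAS/LPS flip composed with the first-voxel offset.
This is the standard DICOM construction; the exact convention used by any
particular planning/navigation software pair can be injected by supplying a
different `Transform`, and the construction is deliberately exposed as its
own function for that reason.

A note on the recalculation: the pre-registration correction is sometimes
written with a transposed registration matrix. The literal transpose of a
homogeneous 4×4 with nonzero translation is not a valid rigid map; the
operation implemented is the rigid inverse, which coincides with the
transpose exactly in the zero-translation case (unit-tested) and is the only
reading under which the correction undoes the pre-registration. The splint
centroid — the origin of the distance covariate — is the arithmetic mean of
the splint mesh vertices, which is one reasonable reading of an undefined
"centroid of the splint".

## Registration baselines

Point-based registration is the closed-form least-squares rigid fit: SVD of
the cross-covariance of centered point pairs with a determinant correction,
so the solution is always a proper rotation even for mirrored inputs.
Configurations with fewer than 3 points, or whose second singular value is
below 1e−6 of the first (collinear), are rejected; coplanar sets — the
clinically realistic case — are fine. `register_point_based_numeric` solves
the same objective by numerical least squares over a rotation-vector
parameterization with random restarts; it shares no code path with the SVD
solution and exists purely as an independent cross-check.

Surface registration is point-to-surface ICP: exact closest points on mesh
triangles (barycentric region walk, vectorized; equidistant ties break to
the lowest face index for determinism), optional worst-fraction trimming
(default off), and a full rigid re-fit from the original probe points to the
correspondences each iteration, which makes the RMS residual non-increasing.
Meshes above 256 faces are queried through a cached KD-tree over face
centroids (64 candidate faces per query). Iteration stops when the RMS
changes by less than 1e−6 mm (default) or at 200 iterations;
non-convergence is reported in the result, not raised. The initial pose must
be supplied: the commercial system's surface-matching start pose and
sampling pattern are unspecified, so both are configurable simulation
parameters rather than claims about any device.

## The synthetic study

No measured cadaver dataset is available, so the simulator reproduces the
*structure* of the accuracy experiment. One phantom per cadaver contains:

* 5 maxillary fiducial screws in a ~40×25 mm patch with craniocaudal spread
  ≤ 5 mm — near-coplanar, as clinical placement dictates;
* 14 target screws at the named cranial landmarks (orbital rim, zygoma,
  lateral orbital wall, porion, nasion, frontal, cranium, occipital;
  bilateral pairs exactly mirrored), spanning roughly 40–180 mm from the
  splint centroid;
* a splint-borne DRF whose design-side pose `T_SPL→IPS` and the DICOM
  geometry are derived *consistently* with the ground-truth CT pose, so the
  chain itself is error-free by construction and all simulated error comes
  from the noise model;
* an ellipsoidal skin mesh (icosphere, semi-axes 72/95/110 mm) for ICP —
  adequate conditioning, no anatomical fidelity claimed.

Noise magnitudes are configuration, not study-derived values (the study
reports only resulting accuracy, never a per-source budget): per-axis
fiducial localization SD 0.25 mm (optical) / 0.30 mm (EM), splint seating
0.2° / 0.3 mm, pointer acquisition 0.15 mm. They land simulated TRE in the
study's ~1–2 mm range for the point-based arms without being fitted to it.
Two arms are known to be optimistic relative to real data: the surface-based
arm, because iid probe noise averages out over 40 probes while real
soft-tissue registration error is dominated by systematic skin deformation,
which is not modeled; and the optical registration-free arm, because the
mechanism behind the large optical-specific error observed in practice
(possibly DRF-arm flexibility) is unexplained and therefore not modeled
either. Passing tests demonstrate the pipeline's algebra and statistics, not
tracker physics.

Each acquisition session runs the *actual* pipeline: bone-anchored arms fit
a real registration to noise-perturbed fiducials, surface arms run real ICP
from a start pose perturbed at the seating SDs (so the zero-noise identity
holds exactly), and the registration-free arm records coordinates under an
arbitrary random rigid pre-registration that the recalculation must undo.
Randomness uses one master seed with per-session substreams derived by
stable hashing of the (cadaver, technique, method, observer, repetition)
tuple, making datasets independent of enumeration order. Missing data is an
explicit index list (the reference design drops 4 registration-free
records, giving 1396/3496), not random dropout, so bookkeeping is exactly
reproducible.

The first-order TRE prediction used as the simulation oracle is

TRE²rms(r) = (FLE²rms / N) · (1 + ⅓ Σₖ dₖ²/fₖ²),

with dₖ the target's distance from fiducial principal axis k and fₖ the RMS
fiducial distance from that axis. For a near-coplanar patch one fₖ is small,
which is precisely the mechanism by which TRE grows with distance from the
registration centroid. Monte-Carlo RMS TRE from the session simulator
matches this within ~1–2% at 2000 repetitions.

## The √TRE mixed model

TRE distributions are right-skewed; √TRE is much closer to Gaussian, so the
model response is √TRE (√mm). Fixed effects: tracking technique, method,
centered target distance, and their interactions, dummy-coded against the
optical/bone-anchored reference. Surface-based registration exists only
with EM tracking, so that cell is structurally absent: no technique:surface
term is estimated, and identically-zero columns are dropped from the design
matrix (aliased columns are reported as singular terms). The distance
covariate is each target's distance to the splint centroid minus the mean
infraorbital-rim distance, so the intercept is the expected √TRE at the
orbital rim; when phantoms differ per cadaver, covariates are computed
against each cadaver's own geometry. Centering means adding any constant to
all distances changes no group line.

Estimation is REML (plain ML available) via statsmodels MixedLM with a
random intercept per cadaver. The original analysis does not state its
random-effects structure, so a second option adds observer and target
variance components; statsmodels has no true crossed random effects, so
these are nested within cadaver — a documented approximation. t values are
reported as estimate/SE without small-sample correction, matching the
reported columns. The optimizer ladder (default, then Powell, then L-BFGS)
accepts the first converged fit whose standard errors are finite and sane;
a candidate whose random-effects covariance collapses and absorbs fixed
effects (symptom: absurd SEs) is rejected. A zero-variance response is
solved exactly (intercept = the constant, all else 0) rather than fed to
the optimizer. Boundary-of-parameter-space notes (cadaver variance → 0) are
reported as diagnostics, not failures.

Group lines are exact linear recombinations of the coefficient table
(reference group: intercept and distance alone; other groups add their main
effects and interactions) and are reported at 2 decimals (intercepts) and 4
decimals (slopes). Distribution summaries use Freedman–Diaconis histogram
bins and a Gaussian KDE with Silverman bandwidth on a grid extending 5
bandwidths past the data; above-threshold proportions use strict
inequality. Skewness of TRE and √TRE is always reported side by side, since
the transform's normalizing effect motivates the model scale.

## Problem sizes and determinism

Default analysis sizes match the reference design (3496 records). The
registration cross-check uses 100 random ≤8-point problems; the Monte-Carlo
theory comparison uses 2000 repetitions at five target distances, where the
RMS standard error (~1.6%) sits comfortably inside the 3% comparison band.
Every stochastic component is seeded; the acceptance script derives all of
its randomness from its single `--seed` argument.

## Known limitations

* No deformable or probabilistic registration; ICP is plain rigid
  point-to-surface with optional trimming.
* The skin mesh and noise model do not emulate tracker physics (EM field
  distortion, camera occlusion) or tissue deformation.
* The proprietary acquired-landmark DICOM dialect of the navigation system
  is not parsed; acquired landmarks use the documented CSV/JSON schema.
* Crossed random effects are approximated as nested variance components.
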