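# Methods

## Geometry and coordinate conventions

All computations are landmark-based; no bone surfaces are modelled.  A leg
is ten named 3D points (FHC, FKC, TKC, AJC, PLP, PMP, MPT, LPT, ME, LE) plus
an epicondylar surface point cloud, in millimetres.  The world frame of a
neutral-positioned right-convention leg is right-handed with +x medial,
+y anterior, +z cranial; the radiographic detector is the x–z plane and
projection is orthographic (parallel X-rays), i.e. the y coordinate is
dropped.  Left legs are mirrored across x = 0 before any measurement and the
mirror is undone afterwards, so medial/lateral signs are side-independent.
With these conventions a lateralized patella has a negative patellar
position, HKA < 180° is varus, and a mechanical axis passing medial to the
knee centre gives positive MAD.

The anatomical frame is built from a nonlinear least-squares cylinder fit
of the epicondylar cloud (axis point + direction + radius, minimising
radial residuals).  The fit is initialised from the cloud's principal
direction, with the axis-point offset and radius seeded by an algebraic
(Kasa) circle fit in the perpendicular plane; convergence tolerances are
1e−12 on parameters and cost.  The frame's x-axis is the fitted cylinder
axis (signed medial using ME − LE), z is the component of FHC − FKC
orthogonal to x, y = z × x, and the origin is the axis point midway between
the cloud's extremal axial projections — a stable reading of "centre of the
epicondylar cylinder".  Aligning maps this frame onto the world axes; the
operation is rigid and idempotent to numerical precision.

Axial rotation is applied, by default, about the frame's longitudinal
(z) axis.  Rotation about the FHC–AJC mechanical line is available as a
configuration option (`rotation_axis="mechanical"`); a regression test pins
the difference between the two choices.  The frame axis is the default
because every closed-form identity used for calibration and testing —
patellar position(θ) = d0·cosθ − a·sinθ, centralizing rotation
atan(d0/a) — is exact for it, and because the mechanical-line alternative
shifts the fitted MPTA response by about +0.01°/° through the oblique
plateau line, which is far from negligible at the scale of the reported
effects.  Positive θ is external rotation: an anterior patella moves
laterally.

The knee centre used for MAD is FKC; the FKC–TKC midpoint is available via
`knee_centre="midpoint"`.  The centralizing rotation is found by bisection
of the projected patellar position on the bracket [−30°, +10°] to 0.001°,
wide enough for the most lateralized patellae; a bracket without a sign
change is reported as non-centralizable rather than raised.

## Synthetic cohort generator

The generator emulates a cohort of 30 subjects (both legs, 60 total) whose
zero-position statistics match the study conditions: HKA 180.1° ± 3.1°,
MPTA 87.7° ± 2.6°, patellar lateral offset −8.3 mm ± 5.4 mm.  Each leg is
built directly in its neutral pose:

* femoral mechanical axis (FKC→FHC, length 430 mm) along +z; the
  transepicondylar cylinder axis (radius 22 mm) along +x through FKC.  The
  frame contract (FHC and FKC on the longitudinal axis after alignment)
  forces the femoral axis to be perpendicular to the cylinder axis, so all
  sampled coronal deviation is carried by the tibia;
* tibial mechanical axis (TKC→AJC, length 380 mm) leaning medially by
  180.1° − HKA in the coronal plane and posteriorly by the calibrated
  tibial sagittal angle (≈1.73°); the tibial segment sits 16 mm anterior to
  the flexion axis, which puts the FHC–AJC line ~2 mm anterior to the knee
  centre (physiological extension alignment) and gives the projected MAD
  response to rotation its clinically observed sign (MAD increases under
  internal rotation, ~−0.04 mm/°);
* plateau line (half-width 38 mm) through TKC, constructed so its projected
  medial angle to the tibial axis equals the sampled MPTA at zero rotation
  for any out-of-plane obliquity;
* patellar poles (pole separation 45 mm) placed so the projected
  zero-position patellar position equals the sampled lateral offset d0 and
  the midpoint sits the sampled anterior offset a in front of TKC;
* epicondylar cloud: 2000 points on a 120° posterior arc of the cylinder
  spanning 60% of an 80 mm intercondylar width, with Gaussian radial noise
  (SD 0.3 mm).  The posterior arc reflects the cylindrical posterior
  condylar surfaces and keeps the cloud's principal direction aligned with
  the cylinder axis, which the fit initialisation relies on.

MAD is never sampled: it emerges from the sampled HKA geometry (≈3.5 mm per
degree of HKA deviation), giving a cohort SD of ~11 mm.  Because the knee
centre is pinned to the frame axis, the emergent MAD mean is near 0 rather
than the 6.2 mm of a real cohort, whose knee centres are offset from the
femoral mechanical axis; a warning is logged if the emergent distribution
leaves the physiological envelope (10 ± 7 mm).

Subject-level random streams are seeded from the pair (master seed, subject
index): cohorts are bit-reproducible, individual subjects re-drawable, and
different master seeds give independent cohorts.  The two legs of a subject
are independent draws (not mirror twins), so the effective sample size is
60; mirror symmetry itself is a tested invariant.

### Correlation structure

Two correlations are not derivable from the reported marginals and were
fixed as design choices:

* **HKA–MPTA correlation 0.85.**  Coronal alignment variation is largely
  tibial in origin: varus knees have low MPTA.  Sampling the two angles
  independently would give the projected joint-line obliquity
  (MPTA − HKA + 90°) an SD of 4°, which makes the per-leg MPTA rotation
  response (proportional to the sine of that obliquity) so variable that a
  60-leg mean slope would fluctuate by ±0.011°/° between cohorts — the
  reported 0.02°/° could not be a stable finding.  The coupling keeps the
  obliquity spread at a realistic ~1.9° while preserving both marginals.
* **Lateral–anterior patellar offset correlation (calibrated, ≈0.89).**
  Controls the cohort-mean centralizing rotation (see calibration).

## Calibration

`calibrate_generator` inverts the closed-form projection geometry so the
default cohort reproduces the headline per-degree effects.  It never runs
the simulation pipeline — calibration and pipeline are independent
implementations, and their agreement is itself a tested property.

* anterior patellar offset mean = |slope target| / sin 1° (≈51.57 mm for
  −0.9 mm/°), so one degree of rotation moves the patella by the target;
  values outside 20–90 mm are rejected as anatomically unreachable.  The
  offset SD is 6.5 mm, chosen so the centralization target is reachable
  within |correlation| < 1 while the pooled regression stays near R² 0.99;
* tibial sagittal angle from the HKA slope target (−0.03°/°) and plateau
  obliquity from the MPTA slope target (+0.02°/°), each by 1D root search
  on the least-squares slope of the closed-form projected angle over the
  ±15° grid (the reported slopes are regression slopes, not derivatives).
  The femoral sagittal angle is fixed at 0: the anatomical frame is built
  from the femoral mechanical axis, so only the femorotibial sagittal
  difference is observable;
* offset correlation from the centralization target (−9.8°) by root search
  on the Gauss–Hermite expectation of atan(d0/a) over the bivariate offset
  distribution.

The calibrated plateau obliquity comes out at ≈ −47°, i.e. the medial
plateau point sits well posterior to the lateral one.  This is an
*effective* parameter: the tibial-axis term alone would give the MPTA the
same response sign as the HKA (−0.03°/°), so the plateau line's
out-of-plane term must both cancel it and supply the opposite sign, and
the lever arm of that term (the sine of the small plateau coronal tilt) is
short.  It reproduces the reported MPTA behaviour at the cost of an
exaggerated literal geometry and a strongly asymmetric MPTA deviation
curve.

## Statistics

Per-leg deviations (value at θ minus value at 0°) are pooled over all legs
and angles.  The patellar model is OLS with intercept on the rotation
degree; using leg-specific deviations implicitly handles the repeated
measures.  HKA, MAD and MPTA deviations are fitted with
`statsmodels.MixedLM` (random intercept per leg, REML): a continuous model
supplies the per-degree slope, and a categorical model on the 5°-increment
subset (reference 0°) supplies the deviation-table cells.  Conditional R²
is (fixed + random variance) / total.  Because every leg's deviation is 0
at the reference angle, the random-intercept variance sits on the boundary;
convergence warnings are suppressed and a flagged pooled-OLS fallback
exists, with an exact zero-slope short-circuit for rotation-invariant
(planar) cohorts.  Mixed-model fixed effects are verified against an
explicit GLS oracle on a 3-leg × 7-angle instance.

The deviation-table patellar row is the regression line evaluated at the
table angles; the inverse estimator divides a patellar shift between two
images by the per-degree slope (−0.9 mm ↔ 1°).

## What the generator does and does not emulate

Passing tests show that the measurement pipeline, the rotation geometry and
the statistical layer reproduce the study's headline numbers on a cohort
*constructed to have* the reported marginal distributions and calibrated
rotation responses.  They do not validate the generator against real
anatomy: femoral bow, condylar twist, patellar tracking against the
trochlea, soft tissue, divergent beams and weight bearing are all absent.
Three known structural departures:

* the emergent MAD mean is ~0 mm (real cohort: 6.2 mm), as explained above;
* the deviation table's HKA row is nearly odd-symmetric (±0.45° at ∓15°),
  while the reported row is asymmetric (0.5° / −0.3°).  The asymmetry is an
  even-in-θ component that requires a cohort-mean coronal lean of ~3° in an
  axis with antero-posterior offset — impossible here because the frame
  contract pins the femoral axis to the rotation axis and the cohort-mean
  tibial lean is fixed by the HKA mean of 180.1°.  The −15° cell matches
  well; the +15° cell sits at the edge of its tolerance;
* the MPTA deviation curve is more curved than reported, a consequence of
  the effective plateau obliquity.

## Problem sizes and tolerances

The default study is 60 legs × 31 positions = 1860 measurements and runs in
a few seconds on one CPU, matching the scale of the emulated study; the
parameter-recovery test uses 1000 legs with light point clouds.  Cylinder
fits recover the true axis to <0.2° under default noise (tested over 100
draws).  Exact geometric identities are asserted at 1e−9–1e−6; cohort-level
statistics at the 2–3 SE bands implied by n = 60.
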