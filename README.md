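# rotalign

Simulation of how axial rotation of the lower limb during radiographic
imaging shifts the projected patellar position and the standard alignment
parameters of long-leg radiographs.

## The problem

Long-leg radiographs (LLRs) are the workhorse of osteotomy and arthroplasty
planning, but there is no consensus on limb positioning during acquisition:
"true AP" protocols centre the patella between the femoral condyles, while
"knee forward" protocols set the femoral condyles parallel to the detector.
Rotating the limb about its longitudinal axis between these orientations
changes every projected measurement. `rotalign` quantifies that effect on a
synthetic cohort of 3D leg models and provides the inverse tool: estimating
the rotation difference between an image pair from the patellar shift.

For each leg (named 3D landmarks plus an epicondylar surface point cloud):

1. an anatomical frame is built from a least-squares **cylinder fit of the
   femoral epicondyles** (the cylinder axis approximates the knee's flexion
   axis and defines the medial-lateral direction), with the longitudinal
   axis through the femoral notch point (FKC) and femoral head centre (FHC);
2. the leg is rigidly aligned so the epicondyles are parallel to the
   detector — the neutral, knee-forward position;
3. the leg is rotated about its longitudinal axis in 1° steps over ±15°
   (31 positions per leg) and after each step the landmarks are projected
   orthographically onto the coronal plane (parallel X-rays) and measured:

   * **HKA** — medial angle between the mechanical femoral axis (FKC→FHC)
     and mechanical tibial axis (TKC→AJC); 180° neutral, <180° varus;
   * **MPTA** — medial angle between the tibial plateau line (MPT–LPT) and
     the tibial mechanical axis;
   * **MAD** — signed distance from the knee centre to the FHC–AJC line;
   * **patellar position** = [PLP + (PMP − PLP)/2] − [TKC], the
     medial–lateral offset of the patellar midpoint from the tibial knee
     centre (negative = lateralized).

For a patellar midpoint with medial offset `d0` and anterior offset `a`
relative to TKC, rotation by θ gives exactly

    patellar position(θ) = d0·cos θ − a·sin θ ≈ d0 − a·θ,

so the response is almost perfectly linear over ±15°: with the calibrated
anterior offset `a = 0.9/sin 1° ≈ 51.6 mm` the patella moves **−0.9 mm per
degree** of external rotation.  Pooled regression of per-leg deviations on
rotation, and linear mixed models (random intercept per leg) for HKA, MAD
and MPTA, reproduce the reported study statistics.  The synthetic cohort
generator emulates the study conditions (30 subjects, both legs; HKA
180.1° ± 3.1°, MPTA 87.7° ± 2.6°, patellar position −8.3 mm ± 5.4 mm) with
ground truth retained, and its sagittal parameters are calibrated by
closed-form inversion — never by running the pipeline.

## Worked example

```sh
python examples/02_cohort_study.py
```

prints (seed 1):

```
legs: 60, measured positions: 1860
pooled patellar regression: -0.888 mm/deg, R^2 = 0.986
HKA: -0.030 per degree (conditional R^2 0.99)
MAD: -0.041 per degree (conditional R^2 0.92)
MPTA: +0.021 per degree (conditional R^2 0.28)

Deviation from the neutral position by rotation angle:
                         -15  -10  -5    5    10    15
Patellar position (mm)  13.3  8.9  4.4 -4.4 -8.9 -13.3
HKA (deg)                0.4  0.3  0.1 -0.2 -0.3  -0.5
MAD (mm)                 0.7  0.4  0.2 -0.2 -0.4  -0.6
MPTA (deg)              -0.7 -0.3 -0.1  0.1  0.1   0.0

Centralized patella vs knee-forward orientation:
                         rotation_deg  hka_deg  mad_mm  mpta_deg
mean                           -10.31     0.28    0.51     -0.56
sd                               6.31     0.17    0.49      1.00
max_alteration_internal        -25.50    -0.12   -0.12     -4.84
max_alteration_external          3.61     0.68    2.33      0.79
```

Reading the output: the patella moves medially by ~0.89 mm per degree of
internal rotation with an almost perfectly linear pooled fit; the angular
parameters change only a few tenths of a degree over the whole ±15° range;
and centring the patella between the condyles requires on average ~10° of
internal rotation from the knee-forward position, with correspondingly
small alignment alterations.  `examples/01_single_leg_sweep.py` verifies a
single sweep against the closed-form rotation geometry, and
`examples/03_rotation_from_patellar_shift.py` inverts a patellar shift
between two images into the underlying rotation.

A thin CLI wraps the same pipeline:

```sh
rotalign run --seed 1 --out results_dir
rotalign generate --seed 1 --out cohort.json
rotalign analyze cohort.json
```

## Layout

- `src/rotalign/cohort.py` — synthetic cohort generator and closed-form
  calibration
- `src/rotalign/frame.py` — epicondylar cylinder fit and neutral alignment
- `src/rotalign/metrics.py` — coronal projection and the four measurements
- `src/rotalign/sweep.py` — rotation sweep, centralization, cohort comparison
- `src/rotalign/stats.py` — pooled regression, mixed models, deviation tables
- `src/rotalign/io.py` — landmark JSON/CSV formats and the study runner
- `docs/methods.md` — model assumptions, parameters, and known limitations
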