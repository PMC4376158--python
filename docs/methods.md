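# Methods

`ukaspect` implements a standardized evaluation pipeline for SPECT/CT of
painful unicondylar knee arthroplasty (UKA): localized quantification of
delayed-phase bone-tracer uptake, 3D measurement of component position
from anatomical landmarks, and observer-reliability analysis. This note
records the models, conventions and numerical choices behind each stage,
and what the synthetic phantoms do and do not establish.

## The localization scheme

Periprosthetic tracer activity is scored in 24 fixed regions: distal femur
8 (zones medial/lateral × inferior/superior × anterior/posterior), patella
4 (medial/lateral × inferior/superior), proximal tibia 12 (zones
medial/lateral/central-around-stem × superior/inferior ×
anterior/posterior). Region codes concatenate bone letter, zone digit,
axial letter and (femur/tibia only) sagittal letter, e.g. `T3sp`. Three
auxiliary landmark regions (femoral mid-shaft, stem tip, tibial tubercle)
sit outside the scored grid; only the femoral mid-shaft is used, as the
background-ratio denominator.

Each region carries a default summary statistic. Four femoral regions
(`F2ip`, `F1ip`, `F2ia`, `F1sp`) default to the **mean**, the remaining
twenty to the **max**. Because a user may reasonably want a single
statistic throughout (the max is the conventional choice for focal
uptake), `BoxConfig.statistic_override` forces all-max or all-mean; the
per-region table is the default and ships as package data
(`ukaspect/data/scheme.csv`).

## Region geometry

The scheme fixes which regions exist; their physical extents are
configuration. Boxes are oriented with the bone's anatomical frame and
tile half-open intervals along each frame axis:

| parameter | default | meaning |
|---|---|---|
| `femoral_slab_mm`, `tibial_slab_mm` | 10 mm | thickness of each axial slab (two per bone) |
| `zone_width_mm` | 25 mm | ML width of medial and lateral zones |
| `ap_extent_mm` | 40 mm | total AP depth, split anterior/posterior at the frame origin |
| `zone3_ml_width_mm` | 15 mm | ML width of the central tibial (stem) zone |
| `patella_ml_mm` / `patella_ap_mm` / `patella_si_mm` | 30 / 20 / 24 mm | patellar block, split ML and SI at `patella_center` |
| `background_box_mm` | 20 × 20 × 30 mm | femoral shaft background box |
| `background_fraction` | 0.5 | position along the knee-to-head distance |

Defaults are sized for an adult knee and are deliberately conservative
(boxes do not span the whole bone); every value is overridable from TOML,
and unknown keys are rejected rather than ignored. Femoral slabs stack
superiorly from the femoral knee center, tibial slabs distally from the
tibial knee center with the superior slab adjacent to the joint line.
Within a bone the boxes partition a rectangular block, so they are
pairwise disjoint by construction.

**Voxel membership.** A voxel belongs to a box when its center, mapped
into the box's frame, lies in the box interval — min face inclusive, max
face exclusive. There is no interpolation and no partial-volume
weighting: a voxel contributes fully or not at all. To make the half-open
rule exact under floating point, membership is evaluated in frame
coordinates against interval bounds snapped to 1e-9 mm; adjacent boxes
then hold bit-identical boundary values and can never both claim a voxel
whose center lies on a shared face. Partial-volume effects at box
boundaries are a known limitation; at SPECT resolution they are small
relative to the reconstruction blur, which the pipeline does not model.

**Background and ratios.** The background reference is the **mean**
intensity in the femoral mid-shaft box (a reference level should be
noise-robust; the max of a homogeneous shaft region would be biased
upward by noise). Region ratios are `statistic(region) / mean(background)`
and are invariant to global gain: rescaling the whole volume (dose,
scanner calibration) cancels exactly. The region statistic over
background mean pairing is configurable (`background_statistic`).

Note that a **max** statistic is biased upward under additive noise (the
maximum of m noisy voxels sits ≈ sd·√(2·ln m) above the true plateau);
this is a property of the statistic itself, visible in the phantom
studies, not an implementation artifact. Mean-type regions are unbiased
with CLT-rate noise suppression.

## Anatomical frames and component angles

All frames are right-handed orthonormal triads (ml, ap, si) =
(medial→lateral, posterior→anterior, inferior→superior), ml × ap = si.

* **Femur** — si along the mechanical axis (knee center → femoral head
  center); ml from the transepicondylar axis, Gram-Schmidt-orthogonalized
  against si; origin at the femoral knee center.
* **Tibia** — si along the mechanical axis (ankle center → tibial knee
  center); ml from the tibial posterior condylar axis, orthogonalized
  against si; origin at the tibial knee center.
* **Components** — from three fiducials (`origin`, a point along the
  component's ML reference, a point toward its anterior reference),
  orthogonalized the same way. Fiducial triples keep the pose definition
  exact and testable without segmenting metal.

Degeneracy guards: coincident defining points within 1e-6 mm and axes
parallel within 1e-6 rad raise geometry errors rather than producing an
ill-conditioned frame.

**Projected angles.** Every clinical angle is a planar projection: the
vector of interest is projected into a frame plane and measured from a
reference axis with atan2, signed about the plane's oriented normal. The
plane orientations are fixed so positive raw angles run ml→si (coronal),
ap→si (sagittal) and ml→ap (axial). The three component angles are:

* varus–valgus — component si in the coronal plane vs anatomical si;
* flexion–extension (femur) / slope (tibia) — component si in the
  sagittal plane vs anatomical si;
* internal–external rotation — component ml in the axial plane vs the
  transepicondylar axis (femur) or posterior condylar axis (tibia).

The femorotibial **rotational mismatch** is the signed difference
(femoral − tibial axial rotation) wrapped to (−180°, 180°], and the
**tibiofemoral angle** is the coronal projection of the tibial onto the
femoral mechanical axis in the femoral frame.

**Sign conventions.** Published conventions (varus positive, femoral
flexion positive, posterior tibial slope negative, internal rotation
negative) are attached to the raw projected angles through a single
multiplier table (`geometry.SignConvention`), derived once from the
plane-normal geometry of the upright template anatomy. Users who prefer
the opposite convention for any angle flip one multiplier; the phantom
generator consumes the same table, so round-trip consistency is preserved
under any convention. The axial sign is chirality-dependent (a left knee
mirrors it); the default corresponds to a right-knee-like template, and
handedness handling beyond the multiplier table is out of scope.

**Angles are reported in degrees, wrapped to (−180°, 180°]; internal
arithmetic is in radians.**

A note on composition: the three reported angles are independent planar
projections, not Euler angles. For any fixed rotation order the Euler
triple and the projection triple disagree once two angles are nonzero
(second-order in the angles, e.g. the sagittal projection of
R_ap(θc)·R_ml(θs) is atan2(sin θs, cos θc·cos θs), not θs). The phantom
therefore does not compose Euler rotations; it inverts the projections
directly (below), which is exact.

## Phantoms

* **Landmark cases.** Given target angle reports, the generator builds the
  component triad in anatomical coordinates by inverting the measurement:
  the si axis from the tangents of the target coronal and sagittal
  projection angles, the ml axis from the target axial azimuth subject to
  orthogonality, ap completing the triad; the ankle center is displaced in
  the femoral coronal plane to encode the target tibiofemoral angle
  *before* the tibial frame (and hence the tibial component) is built.
  Measurement recovers all seven angles to ~1e-12°, far inside the 1e-6°
  test tolerance. The inverse is well-posed for |angle| < 90°; the
  generator enforces |angle| < 60°, generous for clinical component
  positions. An optional seeded rigid transform moves the whole set to
  exercise frame-invariance.
* **Uptake volumes.** Voxels inside each region box take that region's
  true level, the background box its level, everything else a base level;
  optional additive Gaussian noise (sd in counts) is clipped at zero.
  Gaussian rather than Poisson noise reflects an already-filtered
  delayed-phase reconstruction; a Poisson mode would be a straightforward
  extension. Default truth levels are integer counts (uniform 20–200
  against background 50, base 10), spanning cold (ratio 0.4) to hot
  (ratio 4) regions; integer levels make in-box means exactly
  representable, so the noiseless pipeline recovers every ratio exactly,
  not approximately. Overlapping truth assignments are rejected.
* **Rater tables.** value(i, r, s) = μ + b_i + c_r + e_irs with
  independent Gaussian effects of prescribed variances; the analytic
  one-way ICC σ²_item/(σ²_item+σ²_rater+σ²_residual) rides along as
  metadata. Defaults (item 9, rater 0, residual 1 → ICC 0.9) sit in the
  "very good" band that well-conducted musculoskeletal reliability
  studies report.

All generators are pure functions of (parameters, seed); identical seeds
give bit-identical outputs.

**What the phantoms do not show.** They contain no reconstruction blur,
scatter, attenuation or metal artifacts, no anatomical curvature (regions
are homogeneous plateaus), and no landmark placement error. Passing tests
therefore establish the *computational* correctness of the pipeline —
geometry, statistics, normalization, estimators — not the clinical
accuracy of SPECT/CT uptake values or of observer landmarking, which only
patient studies can address.

## Reliability analysis

Single-measure intraclass correlations are computed from the two-way
ANOVA mean squares of the items × columns matrix:

* one-way: (MSB − MSW) / (MSB + (k−1)·MSW)
* two-way random, absolute agreement: (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))
* two-way mixed, consistency: (MSR − MSE) / (MSR + (k−1)·MSE)

Model assignment follows standard test-retest practice: **intra-observer**
(one rater, two sessions) uses two-way mixed/consistency — a session-level
offset is not a disagreement of the rater with themselves about ordering;
**inter-observer** uses two-way random/absolute agreement — a systematic
offset between raters *is* a disagreement. Both forms, and the one-way
model, are selectable. When observers rated in multiple sessions, the
inter-observer table is collapsed to one column per observer using each
observer's first session by default (mean of sessions by flag).

Numerical choices: negative estimates are reported as computed and
flagged, never clipped (clipping would hide pathological simulations); a
table with zero total variance raises an undefined-ICC error instead of
returning 1 by fiat; variance-component estimates (item, rater, residual)
accompany every result; two-sided 95% F-based confidence intervals use
the exact F pivots for the one-way and consistency forms and the
Satterthwaite approximation for absolute agreement, returning none when
the pivot is degenerate. Values ≥ 0.81 are graded "very good" and
0.61–0.80 "good", the banding conventional in this literature.

Median signed and absolute paired differences complement the ICCs; for
even-length vectors the median is the midpoint of the central order
statistics.

One estimator caveat surfaced by simulation: the combined rotational
mismatch of two signed rotations is *not* the difference of their
population means in general reporting practice (some groups report
magnitude-style summaries); this package defines mismatch strictly as the
signed wrapped difference and leaves any magnitude summary to the caller.

## Problem sizes used in tests and the acceptance script

Phantom volumes are generated at 2–4 mm isotropic spacing (≈ 0.3 M voxels
at 2 mm for the full-leg grid), 1000 landmark cases for the geometric
round trip, 50 random volume/box pairs against the brute-force voxel
oracle, 100 random tables against the ANOVA oracle, and 200 Monte-Carlo
seeds at n = 500 items for ICC recovery. These sizes give numerically
decisive checks (errors at the 1e-9–1e-14 level against tolerances of
1e-6) while keeping the whole suite inside a few minutes on one CPU.

## Known limitations

* No automatic region placement or landmark detection; landmarks are
  inputs.
* No partial-volume weighting at box faces; no SUV or attenuation/scatter
  handling — ratios against the mid-shaft background are the normalization.
* Box defaults are plausibility choices for adult knees, not derived from
  any cohort; site-specific calibration is expected through the TOML
  config.
* The tibial sagittal reference is the tibial mechanical axis; no
  anatomical-shaft-axis variant is provided.
* Left/right chirality of the axial rotation sign is resolved by the
  sign-convention table, not inferred from the landmark set.
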