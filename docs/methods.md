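# Methods

This note records the models, conventions and numerical choices behind
`ctrsa`, and what the simulated validation does and does not demonstrate.

## Coordinate and reporting conventions

All world coordinates are in mm. Voxel index (0,0,0) is the *centre* of
the corner voxel; indices are 0-based and may be fractional;
`world = origin + direction · (index ⊙ spacing)`. NIfTI sform is
preferred over qform when both are set, for deterministic behaviour
across writers.

Axes follow the RSA reporting convention: x transverse (medial–lateral),
y longitudinal (cranial–caudal), z sagittal (anterior–posterior).
Rotations are intrinsic x→y→z Cardan angles in degrees; migration angles
depend on this sequence, which is fixed package-wide. Decomposition
refuses |ry| ≥ 89° (gimbal lock) and directs the caller to the rotation
matrix/quaternion representation instead.

**Translations are reported at the cup marker centroid** — the standard
rigid-body translation convention. When a rotation is present, a
different reference point yields different translation values; for this
reason method-vs-gold comparisons must use the *same* marker subset on
both sides (see "Accuracy" below).

**Migration components are expressed in the anatomical frame** defined by
the pelvic landmark template (each examination carries the estimated
`anatomy_pose` of that template). Without this, components would be
expressed in the reference examination's scanner axes and would depend on
how the subject happened to be oriented — irrelevant when repositioning
is a small shift, but wrong in general. With it, the pipeline is exactly
invariant to arbitrary rigid repositioning, which the property suite
checks end-to-end.

## Rigid fitting and QC metrics

The point fit is the closed-form Kabsch solution (SVD of the
cross-covariance of centred coordinates, reflection-corrected to
det(R)=+1). Degenerate inputs (n < 3, collinear sets, second singular
value ≤ 1e−9 of the first) raise rather than return garbage. Tests
cross-check the fit against an independent rotation-vector least-squares
minimiser and `scipy`'s `align_vectors` to 1e−9.

Two QC diagnostics follow RSA practice; both *annotate* results and
never abort an analysis:

* **mean error** — RMS of the post-fit marker residuals (mm), computed as
  RMS rather than arithmetic mean (the convention is not standardised; a
  mean-centred variant of the precision SD is likewise available by flag).
  Bound 0.35 mm.
* **condition number** — σ_max/σ_min of the n×3 mean-centred coordinate
  matrix, a scale-free scatter diagnostic; +∞ for rank-deficient sets.
  Bound 100 (configurable). It is applied to the pelvic scatter; a bead
  circle (the cup) is planar by construction and intentionally not gated
  on this metric.

## Phantom simulator (the study conditions)

* 9 pelvic beads drawn uniformly in a 60×60×40 mm periacetabular block
  centred 35 mm on the medial side of the cup, with a minimum pairwise
  separation of 8 mm (beads implanted closer could not be told apart at
  this resolution); 9 (cemented) or 12 (uncemented) cup beads equally
  spaced on a 25 mm-radius circle in the liner-opening plane. The pelvic
  scatter stays comfortably below the condition-number bound (checked
  over 50 seeds).
* Jig: translations in 1.0 mm steps along x/y/z and rotations in 1.0°
  steps about x through the cup centre. The default 6-position schedule
  (cumulative settings (0,0,0,0°), (1,0,0,1°), (1,1,0,1°), (1,1,1,2°),
  (2,1,1,2°), (2,2,1,3°)) keeps all settings within ±3 mm/±3° and makes
  the independent pairs 1–2, 3–4, 5–6 exercise x, z and y translations
  plus x rotations.
* Double examinations: 2 series per position; the whole phantom gets an
  independent random rigid pose per (modality, position, series) —
  rotations up to ±10° per axis, translations up to ±20 mm — while the
  cup-to-pelvis pose is untouched.
* CT rendering: grid 0.6×0.6 mm in-plane at 0.3 mm increments. Each bead
  is a 1.0 mm sphere voxelised by ≥3× per-axis supersampling (sub-voxel
  ≤ 0.125 mm with an analytic edge-softening of one sub-voxel), blurred
  by an isotropic Gaussian PSF of σ = 0.4 mm, and added to a 100 HU
  background at 3000 HU object intensity; white Gaussian noise of
  20 HU is superimposed. With this PSF a 1 mm bead shows a peak of
  roughly 1050 HU — intensities are *pre-PSF* object values, as in a
  real scan where small tantalum beads never reach their material HU.
  The field of view is fitted to the posed markers plus a 12 mm margin
  (a fixed-size FOV is available; a marker whose PSF support does not
  fit raises a geometry error naming it). All randomness is keyed off
  the config seed, so renders are bit-identical given a seed.

The renderer conserves integrated signal to <2% of the analytic sphere
volume and is translation-equivariant (shifting the phantom by one voxel
shifts the noiseless image by one voxel), both under test.

What the simulator does *not* model: bone texture, beam hardening and
metal/blooming artefacts, scanner reconstruction kernels, scatter. The
validation figures therefore characterise the geometry/noise chain of
the *method*, not the robustness of detection to clinical artefacts.

## Bead detection and labelling

Detection thresholds at 600 HU (midway between the background and the
blurred bead peak), takes 26-connected components within [2, 120] voxels
and returns intensity-weighted component centroids. Refinement computes
a background-subtracted intensity-weighted centroid over a 2.0 mm-radius
spherical window; the window median estimates the background and only
voxels above background + 2% of the local peak contribute, which
suppresses the noise far from the bead while truncating the symmetric
profile tail without bias. At 2–4 voxels per bead this weighted centroid
is the stable subvoxel estimator; sphere fitting would be
over-parameterised at this sampling.

Labelling matches candidates to an expected template. Rigid motion
preserves pairwise distances, so a coarse alignment is recovered by
congruent-triangle search (up to 40 best-spread template triplets against
all candidate triplets within a 1 mm side tolerance, scored by
mutual-nearest-neighbour inliers, refit on the inliers), followed by an
optimal one-to-one assignment gated at 1.5 mm. Candidates belonging to
the other rigid body are tolerated as outliers; unmatched template ids
are reported missing; two template ids contending for one candidate
raise a labelling error.

One subtlety: equally spaced cup beads form a regular polygon whose
n-fold symmetry makes absolute labels unidentifiable from geometry alone.
The pipeline therefore labels the cup by nearest neighbour against the
nominal cup template carried through the pelvis-estimated pose: jig
offsets (≤ ~4.3 mm over the schedule) stay below half the minimal cup
bead spacing (6.4 mm for 12 beads), so the correspondence is consistent
across examinations, which is all migration needs — the results are
invariant to the arbitrary symmetry class.

## Stereo gold standard

Two focal spots 1000 mm above a uniplanar detector, separated so the
central rays subtend 40° and cross at the stage point 150 mm above the
detector, where each examination's phantom is centred. Calibration is
assumed perfect — the simulator's geometry is known exactly — because the
gold standard is *defined* as measuring the true migration; calibration
error is deliberately out of scope. Measurement error enters as seeded
2D Gaussian noise (SD 0.02 mm) on the detector coordinates; detector
quantisation is not modelled. Reconstruction takes the midpoint of the
common perpendicular of the two back-projected rays and records the ray
skew as a per-marker quality value; ray pairs under 2° raise an
ill-conditioned-geometry error. Marker occlusion is deterministic:
7 of 9 pelvic beads and 6 (cemented) / 4 (uncemented) cup beads remain
visible, emulating what a film reader can actually designate; the
mechanism (silhouette ray-casting) is not simulated.

## Statistics

* `t_quantile(p, dof)` returns the **two-sided** coverage quantile
  `t_{(1+p)/2, dof}` by default — the convention behind the 2.45
  (p=0.95, 6 d.o.f.) and 2.57 (p=0.95, 5 d.o.f.) multipliers; a one-sided
  variant is available.
* Precision: SD of the double-examination differences computed **about
  zero** (the true value), so the n = 6 differences carry 6 d.o.f. and
  the multiplier is t(0.95, 6) ≈ 2.45. A mean-centred variant (n−1
  d.o.f.) is available by flag.
* Accuracy: d = gold − method per component over the series-matched
  pairwise migrations (3 position pairs × 2 series = 6 differences);
  RMS about zero, multiplier t(0.95, n−1) ≈ 2.57 — the multiplier tracks
  n rather than being hard-coded. The CT side of the comparison is
  restricted to the beads visible in both modalities so that both
  methods measure the identical rigid body *and* share the centroid
  reporting point; without this, a jig rotation about the full-circle
  centre appears as a spurious ~0.18 mm translation offset at the
  occluded subset's centroid.
* Components are always summarised element-wise (per axis), never as
  vector norms.
* The normality check (skewness/kurtosis, Shapiro–Wilk, normal Q-Q
  correlation, optional histogram/Q-Q figure) is advisory only and never
  gates a computation.

## Validation experiment and problem sizes

The replicated experiment (`run_experiment`, also behind
`scripts/acceptance.py` and the validation test suite) runs 20
independently seeded cemented-cup studies — 240 rendered volumes of
~10⁷ voxels each — through the full measured pipeline, a scale chosen so
the whole experiment completes in a couple of minutes on a single core
while still giving 120 precision and 120 accuracy differences and 720
rigid-body fits. Child seeds are spawned via `SeedSequence` and kept
below 2³¹.

## Known limitations

* Detection presumes isolated high-contrast beads; beads touching metal
  surfaces with blooming artefacts (common clinically) are neither
  simulated nor handled.
* The weighted-centroid "best-fit centre" is one possible reading of
  bead-centre estimation; alternatives (e.g. model fitting of the
  blurred sphere) could differ at the few-µm level.
* The anatomical reporting frame is defined by the pelvic bead template;
  in a purely clinical setting without a template, components fall back
  to the reference examination's axes.
* The stereo simulator idealises calibration and occlusion; its role is
  a controllable gold standard, not a model of film physics.
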