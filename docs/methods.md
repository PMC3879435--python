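# Methods

## The measurement model

All geometry lives in the specimen's anatomical frame: origin at the
geometric centre of the talus (implemented as the area-weighted centroid of
the talar surface and recorded as such in output metadata), X
anteroposterior (+anterior), Y superoinferior (+superior), Z mediolateral
(+medial for a right ankle, mirrored for a left). The axes follow the
fixture convention of specimen imaging — they come from the alignment the
specimen was mounted in, not from bone shape; only the origin is derived
from the bone.

Fourteen parameters are measured, ten tibio-fibular and four talar
(`morphometry3d.PARAMETERS`). Sagittal quantities (TiAL, TiSR, APG, APA,
MTiTh, MDA, MDV, TaAL, TaR) are defined in the (X, Y) plane, frontal
quantities (TiW, MalW, MLATi, TaW, MLATa) in the (Z, Y) plane. Length
parameters are Euclidean distances between their defining landmarks in the
plane of the relevant view. In the standard pose these equal the
classical axis-component definitions (the landmark pairs share the
orthogonal coordinate), and the distance form is what an observer measuring
between two labeled image points actually obtains — it is also what makes
in-plane rotations exactly distance-preserving, the behaviour the
sensitivity analysis of the 2D arm exhibits. Angles are measured against
the fixed frame/image axes. One consequence is documented rather than
hidden: in-plane rotation of a view rotates the image wholesale, so an
angle measured against the image horizontal changes one-for-one with the
rotation. A convention that re-references angles to anatomy-derived image
features would suppress this; we keep the fixed-axis convention because it
is what unaided reading of a radiograph does.

The same formula kernel (`compute_profile`) evaluates the 3D planes and the
2D detector coordinates, so the two measurement arms differ only by the
perspective projection between them.

### Landmark extraction

The tibial mortise is segmented by smooth-patch region growing: the seed is
the downward-facing face directly superior to the frame origin (always on
the articular surface), and the patch grows across mesh edges whose
dihedral angle is below `mortise_smooth_angle_deg` (default 8°). Growth
stops at the rim creases, which excludes flat distal cortex and keeps the
malleoli unreachable. A, B are the anteroposterior extremes of the patch, V
its proximal vertex, and the mortise edges give the TiW endpoints. The
trochlea is the set of upward-facing talar faces (normal-Y above
`normal_y_thresh`, default 0.1); it is split into mediolateral thirds for
the medial/lateral variants and a narrow central slab — 10% of the width,
matching the slab used for the radius fits — for the central variants.
Exact coordinate ties are broken lexicographically (x, then y, then z), so
extraction is deterministic. Crest vertices are refined by a parabolic fit
along the ridge line (sub-grid peak localisation), which keeps the frontal
talar angle stable to well under 0.1°.

Circle fits (TiSR, TaR) use the algebraic Kåsa solution refined by three
Gauss–Newton steps on the orthogonal-distance residuals; an RMS above 1 mm
flags the fit as unreliable. Sagittal-convention landmarks (A, B, C, D, V
and the central trochlear points) are stored at Z = 0.

### DRR rendering

A point source sits SID = 1000 mm from a flat detector. The lateral view
places the detector against the most lateral fibular point with the
principal ray through the medial malleolus; the frontal view places it
behind the most posterior bone point plus a 25 mm posterior stand-off
representing the calcaneus (the phantom has no hindfoot; the stand-off sets
a realistic bone-to-detector distance and is configurable). Default
detector: 0.35 mm pixels, 512×512 — the pixel pitch is not prescribed by
any reference and is recorded in output metadata.

Each pixel integrates attenuation along its ray at a fixed step (default
half the smallest voxel), sampling the volume by trilinear interpolation.
Specimen poses are carried as metadata — sample positions are rotated into
the volume's unrotated grid, so no regridding loss accumulates. Steps that
straddle the volume boundary are weighted by their inside fraction and
sampled at the clipped midpoint, which keeps the half-voxel step within
0.5% of a 10×-finer reference integration. Intensities are raw line
integrals: no Beer–Lambert conversion, scatter or detector response, since
the analysis uses only geometry.

### 2D labeling

2D landmarks are labeled by projecting the automatically determined 3D
landmarks (and arc sample sets) through the imaging geometry. An optional
snap step moves each label to the nearest detected silhouette-contour point
within a capture radius; the default radius is 0, i.e. the projected
positions are used as-is. Projected labeling is the procedure the study
design itself relies on, and it avoids injecting pixel-quantization noise
into quantities whose pose-sensitivity is exactly zero by geometry. Contour
detection (sub-pixel marching squares on the line-integral image) and
snapping are implemented and tested for use with non-synthetic images.

## The synthetic cohort

Each specimen is an idealized constructive-solid-geometry ankle:

* **talus** — a cylinder-segment dome (axis Z, radius `trochlea_radius`)
  cut by a distal chord plane at the arc half-angle implied by
  `trochlea_arc_length`, with parabolic crest ridges (height 2.5 mm) whose
  peaks sit `trochlea_width` apart; the whole solid is tilted in the
  frontal plane by `talar_frontal_tilt_deg` (= MLATa).
* **distal tibia** — an extruded block (depth `tibial_thickness`, width
  `tibial_width`, height 40 mm) with a concave cylindrical mortise cut
  (radius `tibial_sagittal_radius`, chord `tibial_arc_length`), inclined in
  the sagittal plane by `mortise_inclination_deg` (= APA) about the mortise
  axis, small anterior/posterior ridges placing the profile extremes C and D
  (so MDA and MDV hit their targets after inclination), a tapered shaft, and
  a medial-malleolus ellipsoid; the mortise clears the dome by a 2.5 mm
  joint space, wide enough to resolve radiographically.
* **fibula** — a vertically elongated ellipsoid (semi-axes 7 × 22 × 7 mm)
  whose extra distal drop realizes `mortise_frontal_tilt_deg` (= MLATi) and
  whose lateral pole sets `malleolar_width`.

Meshes are parametric (structured surface grids; prism caps triangulated by
an in-package ear-clipper), so construction landmarks coincide with mesh
vertices to machine precision. The attenuation volume is rasterized
independently from signed-distance functions at 0.625 mm voxels (binary
bone/background levels with a one-voxel partial-volume ramp at the cortex,
which keeps silhouettes sub-voxel accurate and makes the attenuation sum a
direct volume estimator). Cohorts draw each spec field from a normal
distribution truncated at ±3 SD around the population means/SDs of the 3D
parameter table; jointly infeasible draws are rejected and redrawn, and the
cohort generator is reproducible under its seed.

`truth_profile` is computed by running the shared measurement kernel on the
closed-form landmarks and analytically sampled arcs. For canonical
orientations the spot values are exact (TaR equals the construction radius,
MLATa equals the tilt); under cohort tilts the sagittal dome section is
foreshortened by the frontal tilt, and because truth and measurement use
the same central-slab protocol the two arms stay consistent (validated to
lengths < 1%, angles < 0.2° across sampled cohorts).

What the phantoms deliberately do **not** emulate: real cortical/trabecular
texture and noise, soft tissue, cartilage, articular incongruity,
statistical shape variation beyond the parameter table, and the hindfoot.
Passing tests therefore demonstrate the projective-geometry behaviour of
the measurement chain — magnification bias, pose sensitivity, repeatability
structure, correctability — not the performance of edge detection or
landmarking on clinical images.

## Experiments

* **Standard-pose comparison** — per parameter: Shapiro–Wilk normality
  screening (reported, never gating), two-sided paired *t* at α = 0.05 (no
  multiple-testing correction across the 14 parameters), Pearson *R*, and
  OLS regression `3D = a·2D + b`. Degenerate inputs (identical arms, zero
  variance) yield NaN-safe outputs.
* **Sensitivity** — ±6° in 1° steps about each axis: 12 perturbed poses per
  axis plus the shared standard pose, 37 poses per view. Percent error is
  taken against the standard-pose 2D value, so the zero-perturbation row is
  identically zero; absolute errors are reported alongside because percent
  error is ill-conditioned for near-zero baselines (MLATa ≈ 2°). Trends are
  classified by a zero-intercept fit `err = b₁θ + b₂θ²` with coefficient
  significance at α = 0.05 (numerically-zero coefficients are treated as
  insignificant so that exact polynomials classify correctly). Parameters
  undefined at a pose are recorded as missing, never extrapolated.
* **Repeatability** — 10 random poses per specimen (each rotation component
  uniform on [−bound, +bound]; the source protocol states only "random
  errors within the maximum ranges", and uniform is the least-informative
  choice on a bounded range), then ICC(3,k) = (BMS − EMS)/BMS from the
  two-way ANOVA, with the usual qualitative bands (> 0.81 very good, 0.61–0.80
  good, 0.41–0.60 moderate, 0.21–0.40 fair, below poor). Incomplete rows
  are dropped and counted. A constant matrix leaves the ICC undefined and
  raises rather than returning a number.
* **Correction** — the standard-pose regressions applied to 2D measurements
  under random pose errors bounded at 3° and 6°; residual tables report the
  signed mean percent error and the mean absolute percent error (signed
  means can hide dispersion).

The pipeline (`run_study`) fans one study seed out to fixed per-stage
seeds, making every table byte-reproducible.

## Numerical and protocol choices

* Rotation composition: extrinsic, fixed anatomical axes, order X → Y → Z.
  The systematic protocol only ever rotates one axis at a time; for
  combined random poses ≤ 6° the ordering effect is second-order, but the
  convention is fixed and serialized with every pose.
* Perturbation rotations act about the anatomical origin (the talar
  centre), with the imaging chain fixed.
* The reported scalar TaAL/TaR/TaW map to the central (c) arc variants by
  default and are switchable to the medial/lateral variants
  (`MorphometryConfig.variant`).
* TiW is the mean of the anterior- and posterior-edge endpoint distances
  (both edges are defined; a single scalar is reported).
* TiSR is fitted on a central sagittal slab of the mortise 10% of its
  width, TaR on the matching central dome slab.
* Problem sizes: the test suite and the acceptance script run phantoms at
  1.25–2.5 mm voxels with 0.7–1.4 mm detector pixels on 128–256 px images,
  and cohorts of 4–20 specimens; these coarse profiles exercise the same
  code paths as the CT-matched defaults (0.625 mm voxels, 512 px images,
  58 specimens), which remain the library defaults.

## Known limitations

* The tibial-mortise segmentation assumes a mesh whose articular patch is
  smooth at the chosen dihedral threshold; heavily decimated or very noisy
  meshes may need the threshold raised.
* Translational positioning errors and plantar-/dorsiflexion joint-angle
  errors are out of scope (rotational specimen pose errors only).
* No intensity-based 2D–3D registration: landmark labeling is projective
  (with optional contour snapping), and no human-observer variability is
  modelled.
* Percent-error summaries for MLATa are dominated by its small baseline;
  use the companion absolute-error columns for interpretation.
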