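# anklemorph

Simulation of **radiographic ankle morphometry**: how reliably can the
morphological parameters that drive total ankle arthroplasty (TAA) planning —
trochlear radius and width, tibial mortise geometry, malleolar spacing — be
measured on plain radiographs, and how badly do ankle-positioning errors
corrupt them?

Planar radiographs are the routine imaging for pre-surgical sizing, but they
are perspective projections: a structure at depth *d* from the detector with
source-to-image distance SID appears magnified by `SID / (SID − d)`, and a
mal-positioned ankle projects oblique, distorted shapes. `anklemorph`
rebuilds this measurement chain end to end *in silico* so the errors can be
quantified exactly:

1. **Synthetic specimens** (`phantom_cohort`) — constructive-solid-geometry
   ankles (distal tibia with a cylindrical mortise of radius TiSR, fibular and
   medial malleoli, talus with a crested trochlear dome of radius TaR) whose
   14 classical parameters are known in closed form, with cohort-level
   variation drawn around representative adult population means and SDs.
2. **3D gold standard** (`morphometry3d`) — automatic landmark extraction
   from the bone surface meshes in the anatomical frame (origin at the talar
   centre, X anterior / Y superior / Z medial) and parameter measurement:
   e.g. TiAL = |A−B| for the mortise-arc extremes, TiSR from a least-squares
   (Kåsa + Gauss–Newton) circle fit, APA = ∠(AB, X-axis).
3. **DRR rendering** (`drr_projector`) — perspective digitally reconstructed
   radiographs by fixed-step ray casting with trilinear interpolation,
   SID = 1 m, in the standard lateral (M/L) and frontal (A/P) imaging poses.
4. **2D measurement** (`morphometry2d`) — the same parameter definitions
   applied in detector millimetres on the projected landmarks/contours, with
   magnification deliberately uncorrected (that bias is the object of study).
5. **Perturbation experiments** (`perturbation_study`) — the systematic
   ±6°, 1°-interval sweep about each anatomical axis (37 poses per view) and
   randomized repeatability protocols.
6. **Statistics** (`stats_correction`) — paired *t*, Pearson *R*, the
   calibration regressions `3D = a·2D + b`, intraclass correlation
   ICC(3,k) = (BMS − EMS)/BMS, and regression-based correction of perturbed
   2D measurements.

It is intended for researchers studying projective measurement error in
orthopaedic imaging and for validating 2D→3D calibration procedures.

## Worked example

```python
from anklemorph import generate_phantom, measure_bones_3d

phantom = generate_phantom()          # cohort-mean anatomy, exact ground truth
profile, lm, arcs = measure_bones_3d(
    phantom.tibia, phantom.fibula, phantom.talus, phantom.frame)
print(profile.as_series().round(2))
```

```
TiAL     28.41
TiSR     29.07
APG       3.89
APA       7.86
MTiTh    48.20
MDA      10.21
MDV       3.15
TaAL     33.54
TaR      20.58
TiW      32.84
MalW     62.61
MLATi    12.59
TaW      19.89
MLATa     2.31
```

The mesh-based pipeline recovers the construction values exactly: a 28.41 mm
tibial arc of 29.07 mm radius inclined 7.86° to the anteroposterior axis, a
20.6 mm trochlear dome with 19.9 mm crest separation, 62.6 mm malleolar
width, and frontal tip-line angles of 12.59° (malleoli) and 2.31° (trochlea).

Measuring the same specimen on its standard-pose radiographs
(`examples/04_standard_pose_2d_vs_3d.py`) shows the projective signature:
every length inflates by ~4–6% (the magnification at its depth) while APA,
MLATi and MLATa — angles whose defining landmarks share projection depth —
are preserved to numerical precision. The sensitivity sweep
(`examples/05_sensitivity_sweep.py`) shows in-plane rotations leaving lengths
unchanged (TiAL, TiW rows 0.0%) while the small frontal angles swing by tens
to hundreds of percent, and `examples/06_repeatability_and_correction.py`
reproduces the repeatability ranking (lengths: ICC ≈ 1, "very good"; MLATa:
moderate) and shows the standard-pose regressions cutting the length errors
to well under 1% at 3° pose error while failing to rescue the small angles.

Each script in `examples/` is a short narrative of one capability; the CLI
(`anklemorph run|phantom|render`) wraps the same pipeline for shell use.

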