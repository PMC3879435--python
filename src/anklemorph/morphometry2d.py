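"""Measurement of the morphological parameters on DRR images.

The sagittal parameter set (TiAL, TiSR, APG, APA, MTiTh, MDA, MDV, TaAL,
TaR) is measured on the M/L view with image u = anteroposterior and
v = superoinferior; the frontal set (TiW, MalW, MLATi, TaW, MLATa) on the
A/P view with u = mediolateral and v = superoinferior.  The definitions are
identical to the 3D ones, applied in detector millimetres with NO
magnification correction — that projective bias is precisely the object of
study.  Angles are measured against the fixed image axes.

Landmarks are labeled automatically from the projected 3D landmarks; an
optional snap step refines each label to the nearest detected silhouette
contour point within a capture radius (radius 0, the default, keeps the
projected positions — the projective labeling the study itself relies on,
free of pixel-quantization noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure

from .drr_projector import DRRImage, LandmarkSet2D
from .morphometry3d import (
    FRONTAL_LANDMARKS,
    SAGITTAL_LANDMARKS,
    MorphometricProfile,
    compute_profile,
    fit_circle_sagittal,
)

__all__ = [
    "View2D",
    "detect_bone_contours",
    "label_landmarks_2d",
    "fit_arc_from_contour",
    "measure_2d",
    "measure_view_2d",
]


@dataclass
class View2D:
    """Everything measured on one radiographic view: labeled landmarks plus
    the projected arc sample sets used for the radius fits."""

    landmarks: LandmarkSet2D
    arcs: dict[str, np.ndarray] = field(default_factory=dict)
    image: DRRImage | None = None


def detect_bone_contours(
    img: DRRImage,
    threshold: float | None = None,
) -> list[np.ndarray]:
    """Silhouette contours of the radiograph in detector millimetres.

    Contours are extracted at a small fraction of the peak line integral
    (sub-pixel, via marching squares), so for a binary-attenuation phantom
    they trace the projected silhouette of the solids.  Returns a list of
    (N, 2) arrays of (u, v) points, longest first.
    """
    px = np.asarray(img.pixels, dtype=float)
    if px.size == 0 or float(px.max()) <= 0:
        raise ValueError("no edges found: blank DRR image")
    if threshold is None:
        threshold = 0.02 * float(px.max())
    contours = skmeasure.find_contours(px, threshold)
    if not contours:
        raise ValueError("no edges found at the requested threshold")
    nu, nv = px.shape
    sp = img.pixel_spacing
    out = []
    for c in sorted(contours, key=len, reverse=True):
        u = (c[:, 0] - (nu - 1) / 2) * sp
        v = (c[:, 1] - (nv - 1) / 2) * sp
        out.append(np.column_stack([u, v]))
    return out


def label_landmarks_2d(
    contours: list[np.ndarray] | None,
    projected: LandmarkSet2D,
    capture_radius: float = 0.0,
) -> LandmarkSet2D:
    """Label image landmarks from projected 3D landmarks.

    With a positive ``capture_radius`` each landmark snaps to the nearest
    contour point within that radius (ties resolved by contour index then
    point order); otherwise — and whenever no contour point is close
    enough — the projected position is kept, with provenance recorded.
    """
    out = LandmarkSet2D()
    if capture_radius <= 0 or not contours:
        for name in projected:
            out.set(name, projected[name], "projected")
        return out
    for name in projected:
        p = projected[name]
        best = None
        best_d = capture_radius
        for ci, c in enumerate(contours):
            d = np.linalg.norm(c - p, axis=1)
            i = int(np.argmin(d))
            # strict inequality keeps the first (lowest contour index) match on ties
            if d[i] < best_d - 1e-12:
                best_d = d[i]
                best = c[i]
        if best is None:
            out.set(name, p, "projected")
        else:
            out.set(name, best, "detected")
    return out


def fit_arc_from_contour(
    contours: list[np.ndarray],
    p_start: np.ndarray,
    p_end: np.ndarray,
    band: float = 2.0,
):
    """Circle fit to detected contour points near the chord p_start--p_end.

    Collects contour points within ``band`` mm of the circle through the
    labeled endpoints (seeded by the direct fit of the gathered points) and
    refits; used when radii are to be measured from image edges rather than
    projected samples.
    """
    p_start = np.asarray(p_start, float)
    p_end = np.asarray(p_end, float)
    chord = np.linalg.norm(p_end - p_start)
    pts = np.concatenate(contours)
    d_ends = np.minimum(np.linalg.norm(pts - p_start, axis=1),
                        np.linalg.norm(pts - p_end, axis=1))
    near = pts[d_ends < 0.75 * chord]
    if len(near) < 3:
        raise ValueError("not enough contour points near the arc endpoints")
    fit = fit_circle_sagittal(near)
    res = np.abs(np.linalg.norm(near - fit.center, axis=1) - fit.radius)
    kept = near[res < band]
    if len(kept) >= 3:
        fit = fit_circle_sagittal(kept)
    return fit


def measure_view_2d(view: str, data: View2D, variant: str = "c") -> MorphometricProfile:
    """Parameters measurable on a single view (sagittal on ML, frontal on AP)."""
    if view.upper() not in ("ML", "AP"):
        raise ValueError(f"view must be 'ML' or 'AP', got {view!r}")
    if view.upper() == "ML":
        return measure_2d(ml=data, ap=None, variant=variant, allow_partial=True)
    return measure_2d(ml=None, ap=data, variant=variant, allow_partial=True)


def measure_2d(
    ml: View2D | None,
    ap: View2D | None,
    variant: str = "c",
    allow_partial: bool = False,
) -> MorphometricProfile:
    """Evaluate the 14 parameters from labeled 2D landmarks of both views.

    Distances are in detector millimetres (magnification uncorrected);
    angles are against the image horizontal axis.  With ``allow_partial``
    a single view yields only that view's parameter set.
    """
    if ml is None and ap is None:
        raise ValueError("at least one view is required")

    def pts(view_data: View2D | None, names) -> dict[str, np.ndarray]:
        if view_data is None:
            return {}
        return {n: view_data.landmarks[n] for n in names if n in view_data.landmarks}

    sag = pts(ml, SAGITTAL_LANDMARKS)
    fro = pts(ap, FRONTAL_LANDMARKS)
    arcs: dict[str, np.ndarray] = {}
    if ml is not None:
        arcs.update(ml.arcs)
    if not allow_partial and (len(sag) < len(SAGITTAL_LANDMARKS)
                              or len(fro) < len(FRONTAL_LANDMARKS)):
        missing = [n for n in SAGITTAL_LANDMARKS if n not in sag] + \
                  [n for n in FRONTAL_LANDMARKS if n not in fro]
        raise KeyError(f"missing landmark {missing[0]!r}")
    if allow_partial:
        return _partial_profile(sag, fro, arcs, variant)
    return compute_profile(sag, fro, arcs, provenance="2D", variant=variant)


def _partial_profile(sag, fro, arcs, variant) -> MorphometricProfile:
    """Single-view profile: evaluate whatever the available landmarks allow."""
    values: dict[str, float] = {}
    fit_rms: dict[str, float] = {}

    def dist(a, b):
        return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))

    def ang(a, b):
        d = np.asarray(a) - np.asarray(b)
        return float(np.degrees(np.arctan2(abs(d[1]), abs(d[0]))))

    if sag:
        from .morphometry3d import arc_length_through
        A, B = sag["A"], sag["B"]
        values["TiAL"] = dist(A, B)
        values["APG"] = abs(A[1] - B[1])
        values["APA"] = ang(A, B)
        values["MTiTh"] = abs(sag["C"][0] - sag["D"][0])
        values["MDA"] = abs(A[1] - sag["C"][1])
        values["MDV"] = abs(sag["V"][1] - sag["D"][1])
        if "mortise" in arcs and len(arcs["mortise"]) >= 3:
            fit = fit_circle_sagittal(arcs["mortise"])
            values["TiSR"] = fit.radius
            fit_rms["TiSR"] = fit.rms
        values["TaAL_c"] = arc_length_through(sag["F_c"], sag["H_c"], sag["G_c"])
        if "dome_c" in arcs and len(arcs["dome_c"]) >= 3:
            fit = fit_circle_sagittal(arcs["dome_c"])
            values["TaR_c"] = fit.radius
            fit_rms["TaR_c"] = fit.rms
        for suffix in ("m", "l"):
            key = f"dome_{suffix}"
            if key in arcs and len(arcs[key]) >= 3:
                f2 = fit_circle_sagittal(arcs[key])
                values[f"TaR_{suffix}"] = f2.radius
                p = arcs[key]
                try:
                    values[f"TaAL_{suffix}"] = arc_length_through(
                        p[np.argmax(p[:, 0])], p[np.argmax(p[:, 1])], p[np.argmin(p[:, 0])])
                except ValueError:
                    pass
        if f"TaAL_{variant}" in values:
            values["TaAL"] = values[f"TaAL_{variant}"]
        if f"TaR_{variant}" in values:
            values["TaR"] = values[f"TaR_{variant}"]
    if fro:
        values["TiWa"] = dist(fro["MortAntMed"], fro["MortAntLat"])
        values["TiWp"] = dist(fro["MortPostMed"], fro["MortPostLat"])
        values["TiW"] = 0.5 * (values["TiWa"] + values["TiWp"])
        values["MalW"] = dist(fro["FibLat"], fro["TibMed"])
        values["MLATi"] = ang(fro["FibDist"], fro["TibDist"])
        values["TaW_a"] = dist(fro["F_m"], fro["F_l"])
        values["TaW_p"] = dist(fro["G_m"], fro["G_l"])
        values["TaW_c"] = dist(fro["H_m"], fro["H_l"])
        values["MLATa"] = ang(fro["TaVert_m"], fro["TaVert_l"])
        taw_variant = {"m": "a", "l": "p", "c": "c"}[variant]
        values["TaW"] = values[f"TaW_{taw_variant}"]
    return MorphometricProfile(values, provenance="2D", variant=variant,
                               landmarks={k: np.asarray(v).tolist() for k, v in
                                          {**sag, **fro}.items()},
                               fit_rms=fit_rms)
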