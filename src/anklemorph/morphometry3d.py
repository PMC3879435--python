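"""Automatic 3D measurement of the 14 ankle morphological parameters.

The parameter set (units in parentheses) covers the distal tibia/fibula and
the talus:

==========  =================================================================
TiAL (mm)   tibial arc length: distance between the anterior (A) and
            posterior (B) extremes of the tibial-mortise arc, sagittal plane
TiSR (mm)   radius of the fitted A--B mortise arc
APG  (mm)   superoinferior (Y) component of the A--B segment
APA  (deg)  inclination of the A--B segment to the anteroposterior axis
MTiTh (mm)  anteroposterior distance between the tibial profile extremes C, D
MDA  (mm)   superoinferior distance between A and C
MDV  (mm)   superoinferior distance between the mortise vertex V and D
TiW  (mm)   mediolateral mortise width (mean of the anterior- and
            posterior-edge endpoint distances TiWa, TiWp)
MalW (mm)   distance between the most lateral fibular point and the most
            medial tibial point, frontal plane
MLATi (deg) frontal angle between the mediolateral axis and the line joining
            the most distal fibular and tibial points
TaAL (mm)   trochlea tali arc length through the anterior (F), proximal (H)
            and posterior (G) trochlear points
TaR  (mm)   fitted sagittal radius of the talar dome
TaW  (mm)   trochlea width between the medial and lateral crests
MLATa (deg) frontal angle between the mediolateral axis and the line joining
            the two proximal trochlear (crest) vertices
==========  =================================================================

F/G/H and the talar widths carry medial/central/lateral (``_m``/``_c``/``_l``)
and anterior/posterior/central (``_a``/``_p``/``_c``) variants; which variant
the scalar report uses is configurable (central by default).

Length parameters are Euclidean distances between their defining landmarks in
the plane of the relevant view; in the standard pose these coincide with the
axis components of the classical definitions.  The same formula kernel
(:func:`compute_profile`) is used for 3D (sagittal/frontal plane projections)
and for 2D radiograph measurements, so the two arms differ only by the
perspective projection under study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bone_models import AnatomicalFrame, LandmarkSet3D, SurfaceMesh

__all__ = [
    "PARAMETERS",
    "UNITS",
    "SAGITTAL_PARAMETERS",
    "FRONTAL_PARAMETERS",
    "CircleFit",
    "MorphometricProfile",
    "MorphometryConfig",
    "fit_circle_sagittal",
    "compute_profile",
    "extract_tibial_landmarks",
    "extract_talar_landmarks",
    "measure_3d",
    "measure_bones_3d",
]

SAGITTAL_PARAMETERS = ["TiAL", "TiSR", "APG", "APA", "MTiTh", "MDA", "MDV", "TaAL", "TaR"]
FRONTAL_PARAMETERS = ["TiW", "MalW", "MLATi", "TaW", "MLATa"]
PARAMETERS = SAGITTAL_PARAMETERS + FRONTAL_PARAMETERS

UNITS = {p: ("deg" if p in ("APA", "MLATi", "MLATa") else "mm") for p in PARAMETERS}

#: landmarks whose parameters live in the sagittal plane (x = anteroposterior,
#: y = superoinferior); stored with z = 0 by convention
SAGITTAL_LANDMARKS = ["A", "B", "C", "D", "V", "F_c", "G_c", "H_c"]
#: landmarks whose parameters live in the frontal plane (z, y)
FRONTAL_LANDMARKS = [
    "FibLat", "TibMed", "FibDist", "TibDist",
    "MortAntMed", "MortAntLat", "MortPostMed", "MortPostLat",
    "F_m", "F_l", "G_m", "G_l", "H_m", "H_l", "TaVert_m", "TaVert_l",
]


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    rms: float

    @property
    def reliable(self) -> bool:
        """Residual RMS below 1 mm marks a trustworthy arc fit."""
        return self.rms < 1.0


def fit_circle_sagittal(points: np.ndarray, refine_steps: int = 3) -> CircleFit:
    """Least-squares circle through 2D points.

    Algebraic (Kåsa) fit followed by a few Gauss-Newton refinement steps on
    the geometric (orthogonal-distance) residuals.  Raises ``ValueError`` for
    fewer than three points or a collinear point set.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("circle fit needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if sv[1] <= 1e-9 * scale:
        raise ValueError("cannot fit a circle to collinear points")
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = math.sqrt(max(sol[2] + cx**2 + cy**2, 0.0))
    # Gauss-Newton on (|p - c| - r)
    for _ in range(refine_steps):
        d = pts - [cx, cy]
        dist = np.linalg.norm(d, axis=1)
        dist = np.where(dist < 1e-12, 1e-12, dist)
        res = dist - r
        J = np.column_stack([-d[:, 0] / dist, -d[:, 1] / dist, -np.ones(len(pts))])
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        cx += step[0]
        cy += step[1]
        r += step[2]
    dist = np.linalg.norm(pts - [cx, cy], axis=1)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit((float(cx), float(cy)), float(r), rms)


def _circumcircle(p1, p2, p3) -> tuple[np.ndarray, float]:
    a = np.asarray(p1, float)
    b = np.asarray(p2, float)
    c = np.asarray(p3, float)
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-12:
        raise ValueError("arc points are collinear")
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def arc_length_through(p_start, p_mid, p_end) -> float:
    """Length of the circular arc from p_start to p_end passing through p_mid."""
    center, radius = _circumcircle(p_start, p_mid, p_end)
    th = [math.atan2(p[1] - center[1], p[0] - center[0]) for p in (p_start, p_mid, p_end)]
    # sweep from start to end in the direction that passes through mid
    sweep = (th[2] - th[0]) % (2 * math.pi)
    mid_off = (th[1] - th[0]) % (2 * math.pi)
    if mid_off > sweep:
        sweep = 2 * math.pi - sweep
    return radius * sweep


# ---------------------------------------------------------------------------
# profile computation (shared 2D/3D kernel)
# ---------------------------------------------------------------------------


@dataclass
class MorphometricProfile:
    """The named parameters with values, units and the landmark snapshot."""

    values: dict[str, float]
    provenance: str = "3D"
    variant: str = "c"
    landmarks: dict | None = None
    fit_rms: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({p: self.values.get(p, np.nan) for p in PARAMETERS}, name=self.provenance)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "variant": self.variant,
            "values": {k: float(v) for k, v in self.values.items()},
            "units": UNITS,
        }


def _dist(p, q) -> float:
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def _angle_to_horizontal(p, q) -> float:
    d = np.asarray(p, float) - np.asarray(q, float)
    return math.degrees(math.atan2(abs(d[1]), abs(d[0])))


def compute_profile(
    sagittal: Mapping[str, np.ndarray],
    frontal: Mapping[str, np.ndarray],
    arcs: Mapping[str, np.ndarray],
    provenance: str = "3D",
    variant: str = "c",
) -> MorphometricProfile:
    """Evaluate the 14 parameters from named 2D points in the sagittal and
    frontal measurement planes plus sampled arc point sets.

    ``sagittal`` maps A, B, C, D, V, F_c, G_c, H_c to (x, y); ``frontal``
    maps the frontal-plane landmarks to (u, y) with u the mediolateral image
    coordinate.  ``arcs`` must contain ``mortise`` and ``dome_c`` (and may
    contain ``dome_m``/``dome_l``) as (N, 2) arrays for the radius fits.
    """

    def sag(name):
        if name not in sagittal:
            raise KeyError(f"missing landmark {name!r}")
        return np.asarray(sagittal[name], float)

    def fro(name):
        if name not in frontal:
            raise KeyError(f"missing landmark {name!r}")
        return np.asarray(frontal[name], float)

    if variant not in ("m", "l", "c"):
        raise ValueError(f"variant must be 'm', 'l' or 'c', got {variant!r}")

    values: dict[str, float] = {}
    fit_rms: dict[str, float] = {}

    A, B, C, D, V = (sag(n) for n in "ABCDV")
    values["TiAL"] = _dist(A, B)
    values["APG"] = abs(A[1] - B[1])
    values["APA"] = _angle_to_horizontal(A, B)
    values["MTiTh"] = abs(C[0] - D[0])
    values["MDA"] = abs(A[1] - C[1])
    values["MDV"] = abs(V[1] - D[1])

    if "mortise" not in arcs or len(np.atleast_2d(arcs["mortise"])) < 3:
        raise KeyError("missing arc point set 'mortise'")
    fit = fit_circle_sagittal(arcs["mortise"])
    values["TiSR"] = fit.radius
    fit_rms["TiSR"] = fit.rms

    # talar sagittal set, per-variant
    for suffix in ("m", "l", "c"):
        src = sag if suffix == "c" else fro
        F, G, H = src(f"F_{suffix}"), src(f"G_{suffix}"), src(f"H_{suffix}")
        if suffix == "c":
            values["TaAL_c"] = arc_length_through(F, H, G)
        else:
            # medial/lateral arcs live in sagittal projection: drop the
            # mediolateral coordinate via the paired sagittal arc samples
            key = f"dome_{suffix}"
            if key in arcs and len(np.atleast_2d(arcs[key])) >= 3:
                f2 = fit_circle_sagittal(arcs[key])
                values[f"TaR_{suffix}"] = f2.radius
                fit_rms[f"TaR_{suffix}"] = f2.rms
    if "dome_c" not in arcs or len(np.atleast_2d(arcs["dome_c"])) < 3:
        raise KeyError("missing arc point set 'dome_c'")
    fit = fit_circle_sagittal(arcs["dome_c"])
    values["TaR_c"] = fit.radius
    fit_rms["TaR_c"] = fit.rms

    # medial/lateral arc lengths from the sagittal-projected m/l dome arcs
    for suffix in ("m", "l"):
        key = f"dome_{suffix}"
        if key in arcs and len(np.atleast_2d(arcs[key])) >= 3 and f"TaR_{suffix}" in values:
            pts = np.atleast_2d(arcs[key])
            i_f = int(np.argmax(pts[:, 0]))
            i_g = int(np.argmin(pts[:, 0]))
            i_h = int(np.argmax(pts[:, 1]))
            try:
                values[f"TaAL_{suffix}"] = arc_length_through(pts[i_f], pts[i_h], pts[i_g])
            except ValueError:
                pass

    # frontal set
    values["TiWa"] = _dist(fro("MortAntMed"), fro("MortAntLat"))
    values["TiWp"] = _dist(fro("MortPostMed"), fro("MortPostLat"))
    values["TiW"] = 0.5 * (values["TiWa"] + values["TiWp"])
    values["MalW"] = _dist(fro("FibLat"), fro("TibMed"))
    values["MLATi"] = _angle_to_horizontal(fro("FibDist"), fro("TibDist"))
    values["TaW_a"] = _dist(fro("F_m"), fro("F_l"))
    values["TaW_p"] = _dist(fro("G_m"), fro("G_l"))
    values["TaW_c"] = _dist(fro("H_m"), fro("H_l"))
    values["MLATa"] = _angle_to_horizontal(fro("TaVert_m"), fro("TaVert_l"))

    # reported scalars per variant
    values["TaAL"] = values.get(f"TaAL_{variant}", values["TaAL_c"])
    values["TaR"] = values.get(f"TaR_{variant}", values["TaR_c"])
    taw_variant = {"m": "a", "l": "p", "c": "c"}[variant]
    values["TaW"] = values[f"TaW_{taw_variant}"]

    snapshot = {k: np.asarray(v, float).tolist() for k, v in {**sagittal, **frontal}.items()}
    return MorphometricProfile(values, provenance=provenance, variant=variant,
                               landmarks=snapshot, fit_rms=fit_rms)


# ---------------------------------------------------------------------------
# landmark extraction from meshes
# ---------------------------------------------------------------------------


@dataclass
class MorphometryConfig:
    """Explicit thresholds for articular-surface classification.

    ``normal_y_thresh``
        minimum |Y component| of the face normal for a face to count as
        mortise- (downward) or trochlea- (upward) facing.
    ``mortise_smooth_angle_deg``
        dihedral-angle limit for the region growing that segments the
        mortise patch; growth stops at surface creases sharper than this.
    ``sagittal_slab_frac``
        half-width of the central sagittal slab used for the radius fits and
        central landmarks, as a fraction of the structure's mediolateral
        width (0.05 = a slab 10% of the width).
    """

    normal_y_thresh: float = 0.1
    mortise_smooth_angle_deg: float = 8.0
    sagittal_slab_frac: float = 0.05
    edge_tol_mm: float = 0.8
    ridge_refine: bool = True
    side: str = "right"
    variant: str = "c"

    @property
    def medial_sign(self) -> float:
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        return 1.0 if self.side == "right" else -1.0


def _argext_lex(points: np.ndarray, key: np.ndarray, mode: str,
                tie_x: float = 1.0) -> int:
    """Index of the extremal ``key``; exact ties are broken deterministically
    by lexicographic (x, then y, then z) order.  ``tie_x`` flips the x
    preference (e.g. posterior-edge landmarks prefer the smaller x)."""
    signed = key if mode == "max" else -key
    order = np.lexsort((points[:, 2], points[:, 1], tie_x * points[:, 0], signed))
    return int(order[-1])


def _classified_vertices(
    mesh: SurfaceMesh,
    frame: AnatomicalFrame,
    face_condition,
) -> np.ndarray:
    """Vertices (frame coordinates) of all faces satisfying ``face_condition``.

    Classification is face-based: face normals are crisp at sharp edges,
    so landmarks sitting exactly on patch boundaries (arc ends, crest rims)
    are retained, which vertex-averaged normals would blur away.
    ``face_condition(centers, normals)`` receives frame-coordinate face
    centers and unit normals and returns a boolean mask.
    """
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError(f"empty mesh for bone {mesh.label!r}")
    tm = mesh.as_trimesh()
    centers = frame.to_frame(np.asarray(tm.triangles_center))
    normals = frame.rotate_directions(np.asarray(tm.face_normals))
    mask = face_condition(centers, normals)
    vidx = np.unique(mesh.faces[mask])
    return frame.to_frame(mesh.vertices[vidx])


def _frame_vertices(mesh: SurfaceMesh, frame: AnatomicalFrame) -> np.ndarray:
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError(f"empty mesh for bone {mesh.label!r}")
    return frame.to_frame(mesh.vertices)


def extract_tibial_landmarks(
    tibia: SurfaceMesh,
    fibula: SurfaceMesh,
    frame: AnatomicalFrame,
    config: MorphometryConfig | None = None,
) -> tuple[LandmarkSet3D, dict[str, np.ndarray]]:
    """Tibial/fibular landmarks and the mortise arc sample set.

    The mortise (the distal concave articular surface) is segmented by
    smooth-patch region growing: starting from the downward-facing face
    directly above the talar dome apex (the joint line), the patch grows
    across mesh edges whose dihedral angle stays below
    ``mortise_smooth_angle_deg``.  Creases stop the growth at the arc rims,
    so flat distal cortex is excluded and the malleolus is never reached.
    A/B/V and the mortise edges are extremes of the patch, C/D are the
    global sagittal-profile extremes, and the malleolar landmarks are
    per-bone mediolateral/distal extremes.

    The seed is the downward face directly superior to the frame origin,
    i.e. above the talar centre, which always lies on the mortise.
    """
    cfg = config or MorphometryConfig()
    med = cfg.medial_sign
    vt = _frame_vertices(tibia, frame)
    vf = _frame_vertices(fibula, frame)

    tm = tibia.as_trimesh()
    centers = frame.to_frame(np.asarray(tm.triangles_center))
    normals = frame.rotate_directions(np.asarray(tm.face_normals))
    down = normals[:, 1] < -cfg.normal_y_thresh
    if not down.any():
        raise ValueError("no vertices classified as tibial mortise "
                         "(no downward-facing tibial surface)")

    cand_idx = np.flatnonzero(down)
    horiz = np.linalg.norm(centers[cand_idx][:, [0, 2]], axis=1)
    seed = int(cand_idx[np.argmin(horiz)])

    # adjacency graph restricted to downward faces and smooth edges
    adjacency = np.asarray(tm.face_adjacency)
    angles = np.asarray(tm.face_adjacency_angles)
    ok = (angles < math.radians(cfg.mortise_smooth_angle_deg)) \
        & down[adjacency[:, 0]] & down[adjacency[:, 1]]
    nbrs: dict[int, list[int]] = {}
    for (f0, f1) in adjacency[ok]:
        nbrs.setdefault(int(f0), []).append(int(f1))
        nbrs.setdefault(int(f1), []).append(int(f0))
    patch = {seed}
    stack = [seed]
    while stack:
        f = stack.pop()
        for g in nbrs.get(f, ()):
            if g not in patch:
                patch.add(g)
                stack.append(g)
    vidx = np.unique(tibia.faces[sorted(patch)])
    mortise = vt[vidx]
    if len(mortise) < 3:
        raise ValueError("no vertices classified as tibial mortise "
                         "(mortise patch degenerate)")

    lm = LandmarkSet3D()
    iA = _argext_lex(mortise, mortise[:, 0], "max")
    iB = _argext_lex(mortise, mortise[:, 0], "min")
    iV = _argext_lex(mortise, mortise[:, 1], "max")
    lm["A"] = (mortise[iA, 0], mortise[iA, 1], 0.0)
    lm["B"] = (mortise[iB, 0], mortise[iB, 1], 0.0)
    lm["V"] = (mortise[iV, 0], mortise[iV, 1], 0.0)

    iC = _argext_lex(vt, vt[:, 0], "max")
    iD = _argext_lex(vt, vt[:, 0], "min")
    lm["C"] = (vt[iC, 0], vt[iC, 1], 0.0)
    lm["D"] = (vt[iD, 0], vt[iD, 1], 0.0)

    # mortise edges -> TiW endpoints (the patch spans the full mortise width)
    for edge, x_ref, mode in (("MortAnt", mortise[iA, 0], "max"),
                              ("MortPost", mortise[iB, 0], "min")):
        if mode == "max":
            sel = mortise[mortise[:, 0] >= x_ref - cfg.edge_tol_mm]
            tie = 1.0
        else:
            sel = mortise[mortise[:, 0] <= x_ref + cfg.edge_tol_mm]
            tie = -1.0
        iM = _argext_lex(sel, med * sel[:, 2], "max", tie_x=tie)
        iL = _argext_lex(sel, med * sel[:, 2], "min", tie_x=tie)
        lm[f"{edge}Med"] = sel[iM]
        lm[f"{edge}Lat"] = sel[iL]

    # malleolar extremes per bone label
    iTM = _argext_lex(vt, med * vt[:, 2], "max")
    lm["TibMed"] = vt[iTM]
    lm["TibDist"] = vt[_argext_lex(vt, vt[:, 1], "min")]
    lm["FibLat"] = vf[_argext_lex(vf, med * vf[:, 2], "min")]
    lm["FibDist"] = vf[_argext_lex(vf, vf[:, 1], "min")]

    # central sagittal slab of the mortise for the TiSR fit
    width = mortise[:, 2].max() - mortise[:, 2].min()
    half = max(cfg.sagittal_slab_frac * width, 1.0)
    mid = 0.5 * (mortise[:, 2].max() + mortise[:, 2].min())
    slab = mortise[np.abs(mortise[:, 2] - mid) <= half]
    if len(slab) < 3:
        slab = mortise
    arcs = {"mortise": slab[:, :2].copy()}
    return lm, arcs


def extract_talar_landmarks(
    talus: SurfaceMesh,
    frame: AnatomicalFrame,
    config: MorphometryConfig | None = None,
) -> tuple[LandmarkSet3D, dict[str, np.ndarray]]:
    """Talar landmarks and the sagittal dome arc samples.

    The trochlea is the upward-facing dome (normal line passing near the
    talar centre).  The dome is split into mediolateral thirds; the medial
    and lateral slabs give the F/G/H variants and the crest vertices, a
    narrow central slab gives the central variants and the TaR fit points.
    """
    cfg = config or MorphometryConfig()
    med = cfg.medial_sign

    def is_trochlea(centers, normals):
        return normals[:, 1] > cfg.normal_y_thresh

    troch = _classified_vertices(talus, frame, is_trochlea)
    if len(troch) == 0:
        raise ValueError("no vertices classified as trochlea tali")

    ms = med * troch[:, 2]
    lo, hi = ms.min(), ms.max()
    ext = hi - lo
    if ext <= 0:
        raise ValueError("trochlea has no mediolateral extent")

    lm = LandmarkSet3D()
    arcs: dict[str, np.ndarray] = {}

    def slab_landmarks(mask: np.ndarray, suffix: str):
        pts = troch[mask]
        if len(pts) < 3:
            raise ValueError(f"no trochlear vertices in the {suffix!r} slab "
                             "(degenerate narrow talus?)")
        iF = _argext_lex(pts, pts[:, 0], "max")
        iG = _argext_lex(pts, pts[:, 0], "min")
        iH = _argext_lex(pts, pts[:, 1], "max")
        H = pts[iH].copy()
        if cfg.ridge_refine and suffix in ("m", "l"):
            # restrict the parabolic crest fit to the ridge line itself
            ridge = pts[(pts[:, 1] >= pts[iH, 1] - 1.5)
                        & (np.abs(pts[:, 0] - pts[iH, 0]) <= 1.0)]
            if len(ridge) >= 6 and (ridge[:, 2].max() - ridge[:, 2].min()) > 0.5:
                coef = np.polyfit(ridge[:, 2], ridge[:, 1], 2)
                if coef[0] < -1e-9:
                    z_star = float(np.clip(-coef[1] / (2 * coef[0]),
                                           ridge[:, 2].min(), ridge[:, 2].max()))
                    H = np.array([pts[iH, 0], float(np.polyval(coef, z_star)), z_star])
        if suffix == "c":
            lm["F_c"] = (pts[iF, 0], pts[iF, 1], 0.0)
            lm["G_c"] = (pts[iG, 0], pts[iG, 1], 0.0)
            lm["H_c"] = (H[0], H[1], 0.0)
        else:
            lm[f"F_{suffix}"] = pts[iF]
            lm[f"G_{suffix}"] = pts[iG]
            lm[f"H_{suffix}"] = H
            lm[f"TaVert_{suffix}"] = H
        arcs[f"dome_{suffix}"] = pts[:, :2].copy()

    slab_landmarks(ms >= lo + 2 * ext / 3, "m")
    slab_landmarks(ms <= lo + ext / 3, "l")
    mid = 0.5 * (lo + hi)
    half = max(cfg.sagittal_slab_frac * ext, 0.8)
    slab_landmarks(np.abs(ms - mid) <= half, "c")
    return lm, arcs


def measure_3d(
    landmarks: LandmarkSet3D,
    arcs: Mapping[str, np.ndarray],
    variant: str = "c",
    provenance: str = "3D",
) -> MorphometricProfile:
    """Evaluate the parameter profile from 3D landmarks and arc samples.

    Sagittal quantities use the (X, Y) sagittal-plane projection, frontal
    quantities the (Z, Y) frontal-plane projection — the planes the
    corresponding radiographic views depict.
    """
    sagittal = {name: landmarks[name][[0, 1]] for name in SAGITTAL_LANDMARKS}
    frontal = {name: landmarks[name][[2, 1]] for name in FRONTAL_LANDMARKS}
    return compute_profile(sagittal, frontal, arcs, provenance=provenance, variant=variant)


def measure_bones_3d(
    tibia: SurfaceMesh,
    fibula: SurfaceMesh,
    talus: SurfaceMesh,
    frame: AnatomicalFrame,
    config: MorphometryConfig | None = None,
) -> tuple[MorphometricProfile, LandmarkSet3D, dict[str, np.ndarray]]:
    """Full 3D measurement pipeline: classify, extract, measure."""
    cfg = config or MorphometryConfig()
    lm_t, arcs_t = extract_tibial_landmarks(tibia, fibula, frame, cfg)
    lm_ta, arcs_ta = extract_talar_landmarks(talus, frame, cfg)
    lm = lm_t.copy().update(lm_ta)
    arcs = {**arcs_t, **arcs_ta}
    profile = measure_3d(lm, arcs, variant=cfg.variant)
    return profile, lm, arcs
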