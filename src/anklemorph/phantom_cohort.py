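"""Synthetic ankle phantoms emulating a cadaver-CT morphometry cohort.

Each phantom is an idealized constructive-solid-geometry ankle in the
anatomical frame (X anterior, Y superior, Z medial for a right ankle,
origin at the talar centre):

* **talus** — a cylinder-segment trochlea (axis along Z, radius ``R_ta``)
  cut by a distal chord plane, with raised medial/lateral crest ridges whose
  peaks are ``TaW`` apart; the whole talus may be tilted in the frontal
  plane (the mediolateral inclination MLATa).
* **distal tibia** — an extruded block with a concave cylindrical mortise
  cut (radius ``R_ti``) subtending a configurable arc, small anterior and
  posterior profile ridges (placing the sagittal profile extremes C and D),
  a tapered shaft, and a medial-malleolus ellipsoid; the block is inclined
  in the sagittal plane by the anteroposterior inclination APA.
* **fibula** — a vertically elongated ellipsoid forming the lateral
  malleolus; its extra distal drop realizes the frontal tip-line angle
  MLATi.

The construction is deliberately idealized: the study's claims concern
perspective-projection geometry, which these solids exercise exactly while
keeping every landmark and parameter available in closed form.  Surface
meshes are generated parametrically (no marching cubes), so construction
landmarks coincide with mesh vertices to machine precision; the attenuation
volume is rasterized independently from signed-distance functions with a
one-voxel partial-volume ramp at the cortex.

Ground-truth parameter values (``truth_profile``) are obtained by running
the shared measurement kernel on the closed-form landmarks and arc samples,
so truth and mesh-based measurement agree by construction wherever the mesh
is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate

from ._triangulate import triangulate_polygon
from .bone_models import AnatomicalFrame, LandmarkSet3D, SurfaceMesh, VoxelVolume
from .morphometry3d import MorphometricProfile, measure_3d

__all__ = [
    "PhantomSpec",
    "AnklePhantom",
    "COHORT_TABLE_3D",
    "generate_phantom",
    "generate_cohort",
    "rasterize_phantom",
    "analytic_solid_volume",
]


# mean (SD) of the 3D cohort parameters used for sampling specimen geometry
COHORT_TABLE_3D: dict[str, tuple[float, float]] = {
    "TiAL": (28.41, 2.62),
    "TiSR": (29.07, 8.30),
    "APA": (7.86, 5.40),
    "MTiTh": (42.44, 4.83),
    "MDA": (10.21, 2.47),
    "MDV": (3.15, 1.64),
    "TiW": (32.84, 2.72),
    "MalW": (62.60, 3.69),
    "MLATi": (12.59, 3.08),
    "TaAL": (33.55, 4.54),
    "TaR": (20.57, 2.78),
    "TaW": (19.89, 4.45),
    "MLATa": (2.31, 3.67),
}


@dataclass
class PhantomSpec:
    """Constructive parameters of one synthetic ankle (mm / degrees)."""

    # distal tibia
    tibial_sagittal_radius: float = 29.07   # mortise cylinder radius (TiSR)
    tibial_arc_length: float = 28.41        # mortise chord A-B (TiAL)
    mortise_inclination_deg: float = 7.86   # sagittal block inclination (APA)
    tibial_thickness: float = 42.44         # block anteroposterior depth
    tibial_width: float = 32.84             # block mediolateral width (TiW)
    tibial_height: float = 40.0             # block proximodistal height
    anterior_drop: float = 10.21            # anterior ridge apex above the arc base (MDA)
    posterior_drop: float = 3.15            # posterior ridge apex above the mortise vertex (MDV)
    malleolar_width: float = 62.60          # lateral fibula to medial tibia (MalW)
    mortise_frontal_tilt_deg: float = 12.59  # malleolar tip-line angle (MLATi)
    malleolar_drop: float = 10.0            # tibial malleolus tip below the arc base
    # talus
    trochlea_radius: float = 20.57          # dome radius (TaR)
    trochlea_arc_length: float = 33.55      # central dome arc (TaAL)
    trochlea_width: float = 19.89           # crest-to-crest separation (TaW)
    crest_height: float = 2.5
    talar_frontal_tilt_deg: float = 2.31    # frontal talar tilt (MLATa)
    joint_gap: float = 2.5
    # imaging
    bone_attenuation: float = 1.0
    background_attenuation: float = 0.0
    voxel_spacing: float = 0.625
    side: str = "right"
    # fixed construction details
    ridge_protrusion: float = 3.0
    ridge_halfheight: float = 4.0
    taper_inset: float = 12.0
    fibula_semiaxes: tuple[float, float, float] = (7.0, 22.0, 7.0)
    malleolus_semiaxes: tuple[float, float, float] = (8.0, 10.0, 6.0)
    mesh_edge_length: float = 0.9

    # ----- derived quantities -------------------------------------------

    @property
    def mortise_arc_half_angle_rad(self) -> float:
        return math.asin(self.tibial_arc_length / (2 * self.tibial_sagittal_radius))

    @property
    def mortise_arc_half_angle_deg(self) -> float:
        return math.degrees(self.mortise_arc_half_angle_rad)

    @property
    def trochlea_arc_half_angle_rad(self) -> float:
        return self.trochlea_arc_length / (2 * self.trochlea_radius)

    @property
    def talus_solid_width(self) -> float:
        """Full mediolateral width of the talar solid (crests included)."""
        return 1.5 * self.trochlea_width

    def validate(self) -> None:
        """Raise ``ValueError`` naming the violated invariant."""
        lengths = {
            "tibial_sagittal_radius": self.tibial_sagittal_radius,
            "tibial_arc_length": self.tibial_arc_length,
            "tibial_thickness": self.tibial_thickness,
            "tibial_width": self.tibial_width,
            "tibial_height": self.tibial_height,
            "malleolar_width": self.malleolar_width,
            "trochlea_radius": self.trochlea_radius,
            "trochlea_arc_length": self.trochlea_arc_length,
            "trochlea_width": self.trochlea_width,
            "crest_height": self.crest_height,
            "joint_gap": self.joint_gap,
            "voxel_spacing": self.voxel_spacing,
            "malleolar_drop": self.malleolar_drop,
        }
        for name, v in lengths.items():
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"invariant violated: {name} must be > 0 (got {v})")
        if self.side not in ("right", "left"):
            raise ValueError(f"invariant violated: side must be 'right'/'left' (got {self.side!r})")
        if self.trochlea_width >= self.malleolar_width:
            raise ValueError("invariant violated: trochlea_width must be < malleolar_width")
        for name in ("mortise_frontal_tilt_deg", "talar_frontal_tilt_deg"):
            if abs(getattr(self, name)) > 20.0:
                raise ValueError(f"invariant violated: |{name}| must be <= 20 deg")
        if self.crest_height >= self.trochlea_radius:
            raise ValueError("invariant violated: crest_height must be < trochlea_radius "
                             "(self-intersecting crest geometry)")
        chord_ratio = self.tibial_arc_length / (2 * self.tibial_sagittal_radius)
        if chord_ratio >= math.sin(math.radians(55.0)):
            raise ValueError("invariant violated: mortise arc half-angle exceeds 55 deg "
                             "(tibial_arc_length too large for tibial_sagittal_radius)")
        phi = self.trochlea_arc_half_angle_rad
        if not (math.radians(15.0) <= phi <= math.radians(70.0)):
            raise ValueError("invariant violated: trochlea arc half-angle must lie in "
                             f"[15, 70] deg (got {math.degrees(phi):.1f})")
        if self.tibial_thickness / 2 <= self.tibial_sagittal_radius * chord_ratio + 2.0:
            raise ValueError("invariant violated: tibial_thickness too small for the mortise arc")
        if self.taper_inset >= self.tibial_thickness / 2:
            raise ValueError("invariant violated: taper_inset must be < tibial_thickness/2")
        if self.bone_attenuation <= self.background_attenuation:
            raise ValueError("invariant violated: bone_attenuation must exceed background")
        if self.background_attenuation < 0:
            raise ValueError("invariant violated: background_attenuation must be >= 0")
        geo = _Geometry(self)
        geo.check_clearance()


# ---------------------------------------------------------------------------
# internal construction geometry
# ---------------------------------------------------------------------------


def _rot2(theta: float, pts: np.ndarray, center=(0.0, 0.0)) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    p = np.atleast_2d(pts) - center
    return np.column_stack([p[:, 0] * c - p[:, 1] * s, p[:, 0] * s + p[:, 1] * c]) + center


class _Geometry:
    """Derived construction quantities (pre-recentring coordinates)."""

    def __init__(self, spec: PhantomSpec):
        s = spec
        self.spec = s
        self.alpha = s.mortise_arc_half_angle_rad
        self.theta = math.radians(s.mortise_inclination_deg)
        self.phi = s.trochlea_arc_half_angle_rad
        self.tau = math.radians(s.talar_frontal_tilt_deg)
        self.R_ti = s.tibial_sagittal_radius
        self.R_ta = s.trochlea_radius
        self.c_my = self.R_ta + s.joint_gap - self.R_ti  # mortise cylinder centre height
        self.Y0 = self.c_my + self.R_ti * math.cos(self.alpha)  # arc-base plane
        self.Y1 = self.Y0 + s.tibial_height
        self.xA = self.R_ti * math.sin(self.alpha)
        self.Y_cut = self.R_ta * math.cos(self.phi)  # talar distal chord plane
        self.W_s = s.talus_solid_width
        self.z_in = self.W_s / 6.0        # crest band inner boundary
        self.z_c = s.trochlea_width / 2.0  # crest peak position
        self.w2 = (self.W_s / 2.0 - self.z_in) / 2.0  # crest half-width
        self.V_y = self.c_my + self.R_ti  # mortise vertex height (pose-invariant)
        # ridge apex heights, compensated for the sagittal inclination so the
        # post-rotation drops |y_C - y_A| and |y_D - y_V| hit their targets
        x_apex = s.tibial_thickness / 2.0 + s.ridge_protrusion
        y_A = self.c_my + self.R_ti * math.cos(self.alpha - self.theta)
        cth, sth = math.cos(self.theta), math.sin(self.theta)
        yC_target = (y_A + s.anterior_drop - self.c_my - x_apex * sth) / cth + self.c_my
        yD_target = (self.V_y + s.posterior_drop - self.c_my + x_apex * sth) / cth + self.c_my
        self.taper_start = min(
            max(yC_target - self.Y0, yD_target - self.Y0, 4.0)
            + s.ridge_halfheight + 1.0,
            s.tibial_height - 5.0,
        )
        self.yC0 = float(np.clip(yC_target, self.Y0 + 1.0,
                                 self.Y0 + self.taper_start - 1.0))
        self.yD0 = float(np.clip(yD_target, self.Y0 + 1.0,
                                 self.Y0 + self.taper_start - 1.0))
        # malleoli
        a_m, b_m, c_m = s.malleolus_semiaxes
        self.mall_semis = (a_m, s.malleolar_drop, c_m)
        self.mall_center = np.array([0.0, self.Y0, s.tibial_width / 2.0 + 1.0])
        self.tibmed_z = self.mall_center[2] + c_m
        self.tib_tip_y = self.Y0 - s.malleolar_drop
        a_f, b_f, c_f = s.fibula_semiaxes
        self.fib_semis = (a_f, b_f, c_f)
        fiblat_z = self.tibmed_z - s.malleolar_width
        z_f = fiblat_z + c_f
        dz = self.mall_center[2] - z_f
        drop = dz * math.tan(math.radians(s.mortise_frontal_tilt_deg))
        self.fib_tip_y = self.tib_tip_y - drop
        self.fib_center = np.array([0.0, self.fib_tip_y + b_f, z_f])

    # -- talus crest radius profile
    def crest_radius(self, z: np.ndarray) -> np.ndarray:
        az = np.abs(np.asarray(z, dtype=float))
        bump = 1.0 - ((az - self.z_c) / self.w2) ** 2
        in_band = (az >= self.z_in) & (az <= self.W_s / 2.0)
        return self.R_ta + self.spec.crest_height * np.where(in_band, np.maximum(bump, 0.0), 0.0)

    def theta_max(self, z: np.ndarray) -> np.ndarray:
        r = self.crest_radius(z)
        return np.arccos(np.clip(self.Y_cut / r, -1.0, 1.0))

    # -- tibial cross-section polygon (pre-inclination), CCW
    def cross_section_polygon(self) -> np.ndarray:
        s = self.spec
        D2 = s.tibial_thickness / 2.0
        rp, rh = s.ridge_protrusion, s.ridge_halfheight
        ts = self.Y0 + self.taper_start
        n_arc = max(int(math.ceil(2 * self.alpha * self.R_ti / (0.5 * s.mesh_edge_length))), 24)
        psis = np.linspace(-self.alpha, self.alpha, n_arc + 1)
        # ensure the material point that ends up at the top after inclination
        # is an exact vertex (it becomes the mortise vertex V)
        if abs(self.theta) < self.alpha:
            psis = np.sort(np.unique(np.append(psis, self.theta)))
        arc = np.column_stack([self.R_ti * np.sin(psis),
                               self.c_my + self.R_ti * np.cos(psis)])  # from -alpha to +alpha
        def ridge(sign: float, y_apex: float) -> list[tuple[float, float]]:
            lo = max(y_apex - rh, self.Y0 + 0.3)
            hi = min(y_apex + rh, ts - 0.3)
            pts = [(sign * D2, lo), (sign * (D2 + rp), y_apex), (sign * D2, hi)]
            return pts if sign > 0 else pts  # order fixed by traversal below
        poly: list[tuple[float, float]] = []
        poly.append((-D2, self.Y0))
        poly.append((-self.xA, self.Y0))
        poly.extend(map(tuple, arc))          # -xA up over the vertex to +xA
        poly.append((D2, self.Y0))
        poly.extend(ridge(+1.0, self.yC0))    # anterior ridge, ascending
        poly.append((D2, ts))
        poly.append((D2 - s.taper_inset, self.Y1))
        poly.append((-(D2 - s.taper_inset), self.Y1))
        poly.append((-D2, ts))
        pr = ridge(-1.0, self.yD0)
        poly.extend(pr[::-1])                 # posterior ridge, descending
        arr = np.array(poly, dtype=float)
        # drop consecutive duplicates
        keep = np.ones(len(arr), bool)
        keep[1:] = np.linalg.norm(np.diff(arr, axis=0), axis=1) > 1e-9
        arr = arr[keep]
        if np.linalg.norm(arr[0] - arr[-1]) < 1e-9:
            arr = arr[:-1]
        return _rot2(self.theta, arr, center=(0.0, self.c_my))

    def check_clearance(self) -> None:
        """The inclined mortise arc must stay clear of the talar solid."""
        psis = np.linspace(-self.alpha, self.alpha, 80)
        pos = psis - self.theta  # position angles after inclination
        pts = np.column_stack([self.R_ti * np.sin(pos), self.c_my + self.R_ti * np.cos(pos)])
        zq = np.zeros(len(pts))
        d = _talus_sdf(self, pts[:, 0], pts[:, 1], zq)
        if d.min() < 0.3:
            raise ValueError("invariant violated: mortise arc intersects the talar dome "
                             "(tibial_sagittal_radius / arc / inclination combination infeasible)")
        block_low = self.Y0 - (self.spec.tibial_thickness / 2.0) * abs(math.sin(self.theta))
        if self.tib_tip_y > block_low - 2.0:
            raise ValueError("invariant violated: malleolar_drop too small for "
                             "mortise_inclination_deg (tibial shaft would be most distal)")


def _talus_sdf(geo: _Geometry, x, y, z):
    """Quasi signed distance of the (tilted) talar solid; exact zero set."""
    ct, st = math.cos(geo.tau), math.sin(geo.tau)
    yt = y * ct + z * st
    zt = -y * st + z * ct
    radial = np.sqrt(x**2 + yt**2) - geo.crest_radius(zt)
    return np.maximum.reduce([radial, geo.Y_cut - yt, np.abs(zt) - geo.W_s / 2.0])


# ---------------------------------------------------------------------------
# mesh builders
# ---------------------------------------------------------------------------


def _grid_mesh(vgrid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate an (n, m, 3) structured vertex grid into quads->triangles."""
    n, m, _ = vgrid.shape
    idx = np.arange(n * m).reshape(n, m)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v11 = idx[1:, 1:].ravel()
    faces = np.concatenate([
        np.column_stack([v00, v10, v11]),
        np.column_stack([v00, v11, v01]),
    ])
    return vgrid.reshape(-1, 3), faces


def _merge_meshes(parts: Sequence[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    verts, faces, off = [], [], 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + off)
        off += len(v)
    return np.concatenate(verts), np.concatenate(faces)


def _weld(verts: np.ndarray, faces: np.ndarray, tol: float = 1e-7):
    key = np.round(verts / tol).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    new_faces = inv[faces]
    ok = (new_faces[:, 0] != new_faces[:, 1]) & (new_faces[:, 1] != new_faces[:, 2]) \
        & (new_faces[:, 0] != new_faces[:, 2])
    return verts[first], new_faces[ok]


def _segment_nodes(a: float, b: float, edge: float) -> np.ndarray:
    """Nodes on [a, b] whose arithmetic midpoint is an exact node."""
    n = max(int(math.ceil((b - a) / edge / 2)) * 2, 2)
    return np.linspace(a, b, n + 1)


def _build_talus_mesh(geo: _Geometry) -> tuple[np.ndarray, np.ndarray]:
    s = geo.spec
    e = s.mesh_edge_length
    zs = np.concatenate([
        _segment_nodes(-geo.W_s / 2, -geo.z_in, e)[:-1],
        _segment_nodes(-geo.z_in, geo.z_in, e)[:-1],
        _segment_nodes(geo.z_in, geo.W_s / 2, e),
    ])
    n_th = max(int(math.ceil(2 * geo.phi * geo.R_ta / e)), 16)
    n_th += (n_th % 2)  # even -> odd node count, exact ridge line at theta=0
    sgrid = np.linspace(-1.0, 1.0, n_th + 1)
    thmax = geo.theta_max(zs)
    r = geo.crest_radius(zs)
    TH = sgrid[None, :] * thmax[:, None]
    dome = np.stack([
        r[:, None] * np.sin(TH),
        r[:, None] * np.cos(TH),
        np.broadcast_to(zs[:, None], TH.shape),
    ], axis=-1)
    x_e = np.sqrt(np.maximum(r**2 - geo.Y_cut**2, 0.0))
    T = np.linspace(1.0, -1.0, n_th + 1)
    bottom = np.stack([
        T[None, :] * x_e[:, None],
        np.full((len(zs), n_th + 1), geo.Y_cut),
        np.broadcast_to(zs[:, None], (len(zs), n_th + 1)),
    ], axis=-1)
    parts = [
        _grid_mesh(dome),
        _grid_mesh(bottom),
    ]
    # end caps (convex disk segments) as fans
    for z_end, flip in ((zs[0], False), (zs[-1], True)):
        arc = np.column_stack([
            geo.R_ta * np.sin(sgrid * geo.phi),
            geo.R_ta * np.cos(sgrid * geo.phi),
        ])
        chord_x = math.sqrt(max(geo.R_ta**2 - geo.Y_cut**2, 0.0))
        ring = np.vstack([arc, [[chord_x, geo.Y_cut]], [[-chord_x, geo.Y_cut]]])
        ring = ring[np.argsort(np.arctan2(ring[:, 1] - ring[:, 1].mean(),
                                          ring[:, 0] - ring[:, 0].mean()))]
        center = ring.mean(axis=0)
        v2 = np.vstack([center, ring])
        k = len(ring)
        fan = np.array([[0, 1 + i, 1 + (i + 1) % k] for i in range(k)])
        if flip:
            fan = fan[:, ::-1]
        v3 = np.column_stack([v2, np.full(len(v2), z_end)])
        parts.append((v3, fan))
    verts, faces = _merge_meshes(parts)
    verts, faces = _weld(verts, faces)
    # frontal tilt about the X axis
    ct, st = math.cos(geo.tau), math.sin(geo.tau)
    y, z = verts[:, 1].copy(), verts[:, 2].copy()
    verts[:, 1] = y * ct - z * st
    verts[:, 2] = y * st + z * ct
    return verts, faces


def _build_tibia_mesh(geo: _Geometry) -> tuple[np.ndarray, np.ndarray]:
    s = geo.spec
    poly = geo.cross_section_polygon()
    n = len(poly)
    zs = _segment_nodes(-s.tibial_width / 2, s.tibial_width / 2, 2.0 * s.mesh_edge_length)
    ring3 = np.column_stack([poly, np.zeros(n)])
    levels = np.stack([ring3 + [0, 0, z] for z in zs])  # (nz, n, 3)
    nz = len(zs)
    idx = np.arange(nz * n).reshape(nz, n)
    quads = []
    for j in range(n):
        j2 = (j + 1) % n
        v00 = idx[:-1, j]
        v01 = idx[:-1, j2]
        v10 = idx[1:, j]
        v11 = idx[1:, j2]
        quads.append(np.column_stack([v00, v01, v11]))
        quads.append(np.column_stack([v00, v11, v10]))
    side_faces = np.concatenate(quads)
    verts = levels.reshape(-1, 3)
    cap = triangulate_polygon(poly)
    cap_lo = cap[:, ::-1]            # z = zmin, outward -Z
    cap_hi = cap + idx[-1, 0]        # z = zmax, outward +Z
    faces = np.concatenate([side_faces, cap_lo, cap_hi])
    # medial malleolus ellipsoid, appended as a second closed component
    ell = _build_ellipsoid_mesh(geo.mall_center, geo.mall_semis, s.mesh_edge_length)
    verts, faces = _merge_meshes([(verts, faces), ell])
    return _weld(verts, faces)


def _build_ellipsoid_mesh(center, semis, edge: float) -> tuple[np.ndarray, np.ndarray]:
    a, b, c = semis
    n_lat = max(int(math.ceil(math.pi * b / edge / 2)) * 2, 12)
    n_lon = max(int(math.ceil(math.pi * (a + c) / edge / 4)) * 4, 16)
    lat = np.linspace(-math.pi / 2, math.pi / 2, n_lat + 1)[1:-1]
    lon = np.linspace(0, 2 * math.pi, n_lon, endpoint=False)
    LA, LO = np.meshgrid(lat, lon, indexing="ij")
    ring_v = np.stack([
        a * np.cos(LA) * np.cos(LO),
        b * np.sin(LA),
        c * np.cos(LA) * np.sin(LO),
    ], axis=-1).reshape(-1, 3)
    south = np.array([[0.0, -b, 0.0]])
    north = np.array([[0.0, b, 0.0]])
    verts = np.vstack([south, ring_v, north]) + np.asarray(center)
    faces = []
    def rid(i, j):
        return 1 + i * n_lon + (j % n_lon)
    for j in range(n_lon):
        faces.append([0, rid(0, j + 1), rid(0, j)])
    for i in range(len(lat) - 1):
        for j in range(n_lon):
            faces.append([rid(i, j), rid(i, j + 1), rid(i + 1, j + 1)])
            faces.append([rid(i, j), rid(i + 1, j + 1), rid(i + 1, j)])
    top = len(verts) - 1 - 0
    for j in range(n_lon):
        faces.append([top, rid(len(lat) - 1, j), rid(len(lat) - 1, j + 1)])
    return verts, np.asarray(faces, dtype=np.int64)


def _build_fibula_mesh(geo: _Geometry) -> tuple[np.ndarray, np.ndarray]:
    return _build_ellipsoid_mesh(geo.fib_center, geo.fib_semis, geo.spec.mesh_edge_length)


# ---------------------------------------------------------------------------
# truth landmarks / arcs
# ---------------------------------------------------------------------------


def _truth_landmarks(geo: _Geometry) -> LandmarkSet3D:
    s = geo.spec
    lm = LandmarkSet3D()
    th, al = geo.theta, geo.alpha
    R = geo.R_ti
    c = geo.c_my
    # mortise arc extremes at position angles +-alpha -+ theta
    lm["A"] = (R * math.sin(al - th), c + R * math.cos(al - th), 0.0)
    lm["B"] = (-R * math.sin(al + th), c + R * math.cos(al + th), 0.0)
    lm["V"] = (0.0, geo.V_y, 0.0)
    poly = geo.cross_section_polygon()
    order = np.lexsort((poly[:, 1], poly[:, 0]))
    lm["C"] = (*poly[order[-1]], 0.0)
    lm["D"] = (*poly[order[0]], 0.0)
    W2 = s.tibial_width / 2.0
    A2 = np.asarray(lm["A"][:2])
    B2 = np.asarray(lm["B"][:2])
    lm["MortAntMed"] = (*A2, W2)
    lm["MortAntLat"] = (*A2, -W2)
    lm["MortPostMed"] = (*B2, W2)
    lm["MortPostLat"] = (*B2, -W2)
    lm["TibMed"] = (0.0, geo.mall_center[1], geo.tibmed_z)
    lm["TibDist"] = (0.0, geo.tib_tip_y, geo.mall_center[2])
    lm["FibLat"] = (0.0, geo.fib_center[1], geo.fib_center[2] - geo.fib_semis[2])
    lm["FibDist"] = (0.0, geo.fib_tip_y, geo.fib_center[2])
    # talus (construct untilted, then tilt about X)
    Rt, h = geo.R_ta, s.crest_height
    x_crest = math.sqrt(max((Rt + h) ** 2 - geo.Y_cut**2, 0.0))
    x_c = Rt * math.sin(geo.phi)
    untilted = {
        "F_c": (x_c, geo.Y_cut, 0.0),
        "G_c": (-x_c, geo.Y_cut, 0.0),
        "H_c": (0.0, Rt, 0.0),
        "F_m": (x_crest, geo.Y_cut, geo.z_c),
        "F_l": (x_crest, geo.Y_cut, -geo.z_c),
        "G_m": (-x_crest, geo.Y_cut, geo.z_c),
        "G_l": (-x_crest, geo.Y_cut, -geo.z_c),
        "H_m": (0.0, Rt + h, geo.z_c),
        "H_l": (0.0, Rt + h, -geo.z_c),
    }
    ct, st = math.cos(geo.tau), math.sin(geo.tau)
    for name, (x, y, z) in untilted.items():
        if name.endswith("_c"):
            continue
        lm[name] = (x, y * ct - z * st, y * st + z * ct)
    lm["TaVert_m"] = lm["H_m"]
    lm["TaVert_l"] = lm["H_l"]
    # central-variant landmarks follow the central-slab protocol (the slab is
    # taken in tilted anatomical coordinates, like any measurement would)
    cloud = _dome_cloud(geo)
    c_slab = _dome_slab(cloud, "c")
    lm["F_c"] = (c_slab[np.argmax(c_slab[:, 0])][0],
                 c_slab[np.argmax(c_slab[:, 0])][1], 0.0)
    lm["G_c"] = (c_slab[np.argmin(c_slab[:, 0])][0],
                 c_slab[np.argmin(c_slab[:, 0])][1], 0.0)
    lm["H_c"] = (c_slab[np.argmax(c_slab[:, 1])][0],
                 c_slab[np.argmax(c_slab[:, 1])][1], 0.0)
    return lm


def _dome_cloud(geo: _Geometry) -> np.ndarray:
    """Dense samples of the (tilted) trochlear surface, frame coordinates."""
    zq = np.linspace(-geo.W_s / 2, geo.W_s / 2, 161)
    zq = np.sort(np.unique(np.concatenate([zq, [-geo.z_c, geo.z_c, 0.0]])))
    sq = np.linspace(-1.0, 1.0, 81)
    th = geo.theta_max(zq)[:, None] * sq[None, :]
    r = geo.crest_radius(zq)[:, None]
    x = (r * np.sin(th)).ravel()
    y0 = (r * np.cos(th)).ravel()
    z0 = np.repeat(zq, len(sq))
    ct, st = math.cos(geo.tau), math.sin(geo.tau)
    return np.column_stack([x, y0 * ct - z0 * st, y0 * st + z0 * ct])


def _dome_slab(cloud: np.ndarray, which: str) -> np.ndarray:
    """Mediolateral slab of the dome cloud, mirroring the extraction rule:
    outer thirds for the medial/lateral variants, a narrow central slab
    (10% of the width, at least 1.6 mm) for the central variants."""
    z = cloud[:, 2]
    lo, hi = z.min(), z.max()
    ext = hi - lo
    if which == "m":
        return cloud[z >= lo + 2 * ext / 3]
    if which == "l":
        return cloud[z <= lo + ext / 3]
    mid = 0.5 * (lo + hi)
    return cloud[np.abs(z - mid) <= max(0.05 * ext, 0.8)]


def _truth_arcs(geo: _Geometry) -> dict[str, np.ndarray]:
    pos = np.linspace(-geo.alpha - geo.theta, geo.alpha - geo.theta, 90)
    mortise = np.column_stack([
        geo.R_ti * np.sin(pos), geo.c_my + geo.R_ti * np.cos(pos)
    ])
    cloud = _dome_cloud(geo)
    return {
        "mortise": mortise,
        "dome_c": _dome_slab(cloud, "c")[:, :2],
        "dome_m": _dome_slab(cloud, "m")[:, :2],
        "dome_l": _dome_slab(cloud, "l")[:, :2],
    }


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------


@dataclass
class AnklePhantom:
    """A synthetic specimen: meshes + frame + closed-form ground truth."""

    spec: PhantomSpec
    frame: AnatomicalFrame
    tibia: SurfaceMesh
    fibula: SurfaceMesh
    talus: SurfaceMesh
    truth_landmarks: LandmarkSet3D
    truth_arcs: dict[str, np.ndarray]
    truth_profile: MorphometricProfile
    volume: VoxelVolume | None = None
    meta: dict = field(default_factory=dict)

    @property
    def meshes(self) -> dict[str, SurfaceMesh]:
        return {"tibia": self.tibia, "fibula": self.fibula, "talus": self.talus}

    def ensure_volume(self, voxel_spacing: float | None = None) -> VoxelVolume:
        if self.volume is None:
            self.volume = rasterize_phantom(self, voxel_spacing)
        return self.volume

    def all_vertices(self) -> np.ndarray:
        return np.concatenate([m.vertices for m in self.meshes.values()])


def _area_centroid(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    centers = tri.mean(axis=1)
    return (centers * areas[:, None]).sum(axis=0) / areas.sum()


def generate_phantom(
    spec: PhantomSpec | None = None,
    seed: int = 0,
    with_volume: bool = False,
    voxel_spacing: float | None = None,
) -> AnklePhantom:
    """Build one synthetic ankle from its constructive spec.

    The phantom is recentred so the area-weighted talar surface centroid —
    the anatomical-frame origin — sits exactly at the world origin.  The
    construction itself is deterministic; ``seed`` is recorded for
    provenance and reserved for optional attenuation noise.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    geo = _Geometry(spec)
    tal_v, tal_f = _build_talus_mesh(geo)
    tib_v, tib_f = _build_tibia_mesh(geo)
    fib_v, fib_f = _build_fibula_mesh(geo)
    offset = _area_centroid(tal_v, tal_f)
    lm = _truth_landmarks(geo)
    arcs = _truth_arcs(geo)
    mirror = -1.0 if spec.side == "left" else 1.0

    def fix_mesh(v, f, label):
        v = v - offset
        if mirror < 0:
            v = v * [1.0, 1.0, -1.0]
            f = f[:, ::-1]
        return SurfaceMesh(v, f, label)

    lm_shifted = LandmarkSet3D()
    for name in lm:
        p = lm[name] - offset * (1.0 if name not in ("A", "B", "C", "D", "V",
                                                     "F_c", "G_c", "H_c") else
                                 np.array([1.0, 1.0, 0.0]))
        lm_shifted[name] = p * [1.0, 1.0, mirror]
    arcs_shifted = {k: np.asarray(v) - offset[:2] for k, v in arcs.items()}

    frame = AnatomicalFrame.identity()
    profile = measure_3d(lm_shifted, arcs_shifted, provenance="3D-truth")
    phantom = AnklePhantom(
        spec=spec,
        frame=frame,
        tibia=fix_mesh(tib_v, tib_f, "tibia"),
        fibula=fix_mesh(fib_v, fib_f, "fibula"),
        talus=fix_mesh(tal_v, tal_f, "talus"),
        truth_landmarks=lm_shifted,
        truth_arcs=arcs_shifted,
        truth_profile=profile,
        meta={
            "seed": seed,
            "recentre_offset_mm": offset.tolist(),
            "origin_definition": "area-weighted talar surface centroid",
        },
    )
    if with_volume:
        phantom.volume = rasterize_phantom(phantom, voxel_spacing)
    return phantom


def rasterize_phantom(
    phantom: AnklePhantom,
    voxel_spacing: float | None = None,
    bones: Iterable[str] = ("tibia", "fibula", "talus"),
    margin: float = 3.0,
) -> VoxelVolume:
    """Rasterize the phantom solids into an attenuation volume.

    Attenuation ramps linearly from background to bone over one voxel at the
    surface (a partial-volume edge, matching how CT renders cortex at this
    resolution and keeping silhouettes sub-voxel accurate).
    """
    spec = phantom.spec
    sp = float(voxel_spacing or spec.voxel_spacing)
    geo = _Geometry(spec)
    offset = np.asarray(phantom.meta["recentre_offset_mm"])
    mirror = -1.0 if spec.side == "left" else 1.0
    bones = tuple(bones)
    verts = np.concatenate([phantom.meshes[b].vertices for b in bones])
    lo = verts.min(axis=0) - margin
    hi = verts.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / sp).astype(int) + 1, 2)
    origin = lo
    xs = origin[0] + sp * np.arange(shape[0])
    ys = origin[1] + sp * np.arange(shape[1])
    zs = origin[2] + sp * np.arange(shape[2])
    values = np.empty(tuple(shape), dtype=np.float32)
    th = geo.theta
    cth, sth = math.cos(th), math.sin(th)
    s = spec
    D2 = s.tibial_thickness / 2.0
    ts = geo.Y0 + geo.taper_start
    slope = s.taper_inset / max(geo.Y1 - ts, 1e-9)

    def x_limit(y: np.ndarray, y_apex: float) -> np.ndarray:
        rh, rp = s.ridge_halfheight, s.ridge_protrusion
        tent = np.clip(1.0 - np.abs(y - y_apex) / rh, 0.0, 1.0) * rp
        lim = D2 + np.where((y >= geo.Y0) & (y <= ts), tent, 0.0)
        return np.where(y > ts, D2 - slope * (y - ts), lim)

    for i, xw in enumerate(xs):
        Y, Z = np.meshgrid(ys, zs, indexing="ij")
        X = np.full_like(Y, xw)
        # world -> construction coordinates
        Xc = X + offset[0]
        Yc = Y + offset[1]
        Zc = mirror * Z + offset[2]
        d = np.full(Y.shape, np.inf)
        if "talus" in bones:
            d = np.minimum(d, _talus_sdf(geo, Xc, Yc, Zc))
        if "tibia" in bones:
            xb = Xc * cth + (Yc - geo.c_my) * sth
            yb = -Xc * sth + (Yc - geo.c_my) * cth + geo.c_my
            d_block = np.maximum.reduce([
                geo.Y0 - yb,
                yb - geo.Y1,
                xb - x_limit(yb, geo.yC0),
                -xb - x_limit(yb, geo.yD0),
                geo.R_ti - np.sqrt(xb**2 + (yb - geo.c_my) ** 2),
                np.abs(Zc) - s.tibial_width / 2.0,
            ])
            a, b, c = geo.mall_semis
            cx, cy, cz = geo.mall_center
            d_mall = (np.sqrt(((Xc - cx) / a) ** 2 + ((Yc - cy) / b) ** 2
                              + ((Zc - cz) / c) ** 2) - 1.0) * min(a, b, c)
            d = np.minimum.reduce([d, d_block, d_mall])
        if "fibula" in bones:
            a, b, c = geo.fib_semis
            cx, cy, cz = geo.fib_center
            d_fib = (np.sqrt(((Xc - cx) / a) ** 2 + ((Yc - cy) / b) ** 2
                             + ((Zc - cz) / c) ** 2) - 1.0) * min(a, b, c)
            d = np.minimum(d, d_fib)
        frac = np.clip(0.5 - d / sp, 0.0, 1.0)
        values[i] = s.background_attenuation + (s.bone_attenuation - s.background_attenuation) * frac
    return VoxelVolume(values, (sp, sp, sp), origin)


def analytic_solid_volume(spec: PhantomSpec, bone: str) -> float:
    """Closed-form / quadrature volume (mm^3) of one phantom solid.

    Supports the bones whose volume has a clean analytic form: the talus
    (cross-section area integrated over its width) and the fibula
    (ellipsoid).  Used as an independent oracle for the rasterizer.
    """
    geo = _Geometry(spec)
    if bone == "fibula":
        a, b, c = geo.fib_semis
        return 4.0 / 3.0 * math.pi * a * b * c
    if bone == "talus":
        def area(z: float) -> float:
            r = float(geo.crest_radius(np.array([z]))[0])
            half = math.acos(min(max(geo.Y_cut / r, -1.0), 1.0))
            return r * r * half - geo.Y_cut * math.sqrt(max(r * r - geo.Y_cut**2, 0.0))
        val, _ = integrate.quad(area, -geo.W_s / 2, geo.W_s / 2, limit=200)
        return float(val)
    raise ValueError(f"no analytic volume available for bone {bone!r}")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _spec_from_draw(draw: Mapping[str, float], base: PhantomSpec) -> PhantomSpec:
    return replace(
        base,
        tibial_arc_length=draw["TiAL"],
        tibial_sagittal_radius=draw["TiSR"],
        mortise_inclination_deg=draw["APA"],
        tibial_thickness=draw["MTiTh"],
        anterior_drop=draw["MDA"],
        posterior_drop=draw["MDV"],
        tibial_width=draw["TiW"],
        malleolar_width=draw["MalW"],
        mortise_frontal_tilt_deg=draw["MLATi"],
        trochlea_arc_length=draw["TaAL"],
        trochlea_radius=draw["TaR"],
        trochlea_width=draw["TaW"],
        talar_frontal_tilt_deg=draw["MLATa"],
    )


def sample_specs(
    n: int,
    table: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base: PhantomSpec | None = None,
    max_tries: int = 200,
) -> list[PhantomSpec]:
    """Draw ``n`` valid specimen specs from truncated-normal distributions.

    Each parameter is drawn N(mean, sd) truncated at +-3 SD; a draw whose
    joint combination violates a construction invariant is redrawn.  The
    default table is the 3D cohort mean/SD set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table = dict(table or COHORT_TABLE_3D)
    base = base or PhantomSpec()
    missing = set(COHORT_TABLE_3D) - set(table)
    if missing:
        raise ValueError(f"cohort table is missing parameters: {sorted(missing)}")
    for key, (mean, sd) in table.items():
        if sd < 0:
            raise ValueError(f"invariant violated: SD of {key} must be >= 0")
    try:
        _spec_from_draw({k: m for k, (m, sd) in table.items()}, base).validate()
    except ValueError as e:
        raise ValueError(f"cohort table means are infeasible: {e}") from e
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        last_err: Exception | None = None
        for _try in range(max_tries):
            draw = {}
            for key, (mean, sd) in table.items():
                if sd == 0:
                    draw[key] = mean
                    continue
                v = rng.normal(mean, sd)
                while abs(v - mean) > 3 * sd:
                    v = rng.normal(mean, sd)
                draw[key] = v
            spec = _spec_from_draw(draw, base)
            try:
                spec.validate()
            except ValueError as e:
                last_err = e
                continue
            specs.append(spec)
            break
        else:
            raise ValueError(f"could not draw a feasible specimen spec: {last_err}")
    return specs


def generate_cohort(
    n: int,
    table: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base: PhantomSpec | None = None,
    with_volumes: bool = False,
    voxel_spacing: float | None = None,
) -> list[AnklePhantom]:
    """Generate a reproducible cohort of ``n`` synthetic specimens."""
    if n < 2:
        raise ValueError("a cohort needs n >= 2 specimens")
    specs = sample_specs(n, table=table, seed=seed, base=base)
    return [
        generate_phantom(s, seed=seed + i, with_volume=with_volumes,
                         voxel_spacing=voxel_spacing)
        for i, s in enumerate(specs)
    ]
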