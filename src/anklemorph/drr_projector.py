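"""Perspective digitally-reconstructed-radiograph (DRR) rendering.

A point X-ray source casts rays through the attenuation volume onto a flat
detector 1 m away (the source-to-image distance of a standard digital
radiography system).  Each pixel records the line integral of attenuation
along its ray, sampled at a fixed step with trilinear interpolation; no
detector response or Beer-Lambert conversion is applied, since the
morphometric analysis depends only on the projection geometry.

Standard imaging poses:

* **M/L (lateral) view** — detector plane normal to the mediolateral (Z)
  axis, touching the most lateral fibular point (the lateral malleolus);
  the principal ray passes through the medial malleolus.
* **A/P (frontal) view** — detector normal to the anteroposterior (X)
  axis, touching the most posterior point of the specimen plus a
  configurable posterior offset standing in for the calcaneus; the
  principal ray passes through the midpoint of the inter-malleolar axis.

Specimen pose perturbations rotate the anatomy about the anatomical-frame
origin while the imaging chain stays fixed, exactly as a mal-positioned
ankle would sit in front of a real detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .bone_models import AnatomicalFrame, LandmarkSet3D, RigidPose, SurfaceMesh, VoxelVolume

__all__ = [
    "SID_MM",
    "ProjectionGeometry",
    "DRRImage",
    "LandmarkSet2D",
    "make_standard_geometry",
    "project_point",
    "project_points",
    "project_landmarks",
    "cast_drr",
    "write_drr",
]

#: source-to-image distance (mm): X-ray focus 1 m from the image plane
SID_MM = 1000.0


@dataclass
class ProjectionGeometry:
    """Pinhole source + flat detector model.

    ``det_center`` is the principal point (the foot of the perpendicular
    from the source), placed at the image centre; ``u_axis``/``v_axis``
    span the detector plane and define image (u, v) coordinates in mm.
    """

    source: np.ndarray
    det_center: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    pixel_spacing: float = 0.35
    image_size: tuple[int, int] = (512, 512)  # (nu, nv) pixels
    view: str = ""
    frame_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, float).reshape(3)
        self.det_center = np.asarray(self.det_center, float).reshape(3)
        self.u_axis = np.asarray(self.u_axis, float).reshape(3)
        self.v_axis = np.asarray(self.v_axis, float).reshape(3)
        self.frame_origin = np.asarray(self.frame_origin, float).reshape(3)
        if abs(self.u_axis @ self.v_axis) > 1e-9 or \
           abs(np.linalg.norm(self.u_axis) - 1) > 1e-9 or \
           abs(np.linalg.norm(self.v_axis) - 1) > 1e-9:
            raise ValueError("detector axes must be orthonormal")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.sid <= 0:
            raise ValueError("source must sit in front of the detector (SID > 0)")

    @property
    def normal(self) -> np.ndarray:
        """Unit detector normal pointing towards the source."""
        n = np.cross(self.u_axis, self.v_axis)
        d = self.source - self.det_center
        return n if n @ d > 0 else -n

    @property
    def sid(self) -> float:
        n = np.cross(self.u_axis, self.v_axis)
        return abs(float((self.source - self.det_center) @ n))

    def depth(self, points: np.ndarray) -> np.ndarray:
        """Distance of points from the detector plane along the normal."""
        return np.atleast_2d(points - self.det_center) @ self.normal


@dataclass
class DRRImage:
    """Rendered radiograph: line-integral pixels with mm calibration.

    ``pixels[i, j]`` corresponds to detector coordinate
    ``u = (i - (nu-1)/2) * pixel_spacing``, ``v = (j - (nv-1)/2) * spacing``
    with the principal point at the image centre.
    """

    pixels: np.ndarray
    pixel_spacing: float
    view: str
    pose: RigidPose
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if np.any(self.pixels < 0):
            raise ValueError("DRR intensities must be >= 0")

    @property
    def extent_mm(self) -> tuple[float, float, float, float]:
        nu, nv = self.pixels.shape
        hu = (nu - 1) / 2 * self.pixel_spacing
        hv = (nv - 1) / 2 * self.pixel_spacing
        return (-hu, hu, -hv, hv)

    def uv_grid(self) -> tuple[np.ndarray, np.ndarray]:
        nu, nv = self.pixels.shape
        u = (np.arange(nu) - (nu - 1) / 2) * self.pixel_spacing
        v = (np.arange(nv) - (nv - 1) / 2) * self.pixel_spacing
        return u, v


class LandmarkSet2D:
    """Named detector-plane points (u, v in mm) with labeling provenance."""

    def __init__(self, points: Mapping[str, np.ndarray] | None = None,
                 provenance: str = "projected"):
        self.points: dict[str, np.ndarray] = {}
        self.provenance: dict[str, str] = {}
        if points:
            for k, v in points.items():
                self.set(k, v, provenance)

    def set(self, name: str, value, provenance: str = "projected") -> None:
        self.points[name] = np.asarray(value, float).reshape(2)
        self.provenance[name] = provenance

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise KeyError(f"missing landmark {name!r}")
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def copy(self) -> "LandmarkSet2D":
        out = LandmarkSet2D()
        for k, v in self.points.items():
            out.set(k, v, self.provenance[k])
        return out


def make_standard_geometry(
    view: str,
    meshes: Mapping[str, SurfaceMesh],
    frame: AnatomicalFrame,
    sid: float = SID_MM,
    pixel_spacing: float = 0.35,
    image_size: tuple[int, int] = (512, 512),
    posterior_offset: float = 25.0,
    side: str = "right",
) -> ProjectionGeometry:
    """Standard-pose imaging geometry for the M/L or A/P view.

    ``posterior_offset`` (A/P view only) stands in for the posterior
    calcaneus, which would keep the bones that distance off the detector.
    """
    med = 1.0 if side == "right" else -1.0
    tib = frame.to_frame(meshes["tibia"].vertices)
    fib = frame.to_frame(meshes["fibula"].vertices)
    tibmed = tib[np.argmax(med * tib[:, 2])]
    fiblat = fib[np.argmin(med * fib[:, 2])]
    if view.upper() == "ML":
        z_det = min(m_v for m in meshes.values()
                    for m_v in [np.min(med * frame.to_frame(m.vertices)[:, 2])])
        det_center = np.array([tibmed[0], tibmed[1], med * z_det])
        source = det_center + np.array([0.0, 0.0, med * sid])
        u_axis = np.array([1.0, 0.0, 0.0])
        v_axis = np.array([0.0, 1.0, 0.0])
    elif view.upper() == "AP":
        x_det = min(np.min(frame.to_frame(m.vertices)[:, 0]) for m in meshes.values())
        x_det -= posterior_offset
        mid = 0.5 * (tibmed + fiblat)
        det_center = np.array([x_det, mid[1], mid[2]])
        source = det_center + np.array([sid, 0.0, 0.0])
        u_axis = np.array([0.0, 0.0, 1.0])
        v_axis = np.array([0.0, 1.0, 0.0])
    else:
        raise ValueError(f"view must be 'ML' or 'AP', got {view!r}")
    return ProjectionGeometry(
        source=frame.to_world(source)[0],
        det_center=frame.to_world(det_center)[0],
        u_axis=frame.rotation_matrix().T @ u_axis,
        v_axis=frame.rotation_matrix().T @ v_axis,
        pixel_spacing=pixel_spacing,
        image_size=image_size,
        view=view.upper(),
        frame_origin=frame.origin,
    )


def project_points(points: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    """Central (pinhole) projection of world points onto the detector (u, v mm)."""
    p = np.atleast_2d(np.asarray(points, float))
    n = geom.normal
    denom = (p - geom.source) @ n
    num = float((geom.det_center - geom.source) @ n)
    if np.any(denom * num <= 0):
        raise ValueError("point lies behind the X-ray source")
    t = num / denom
    q = geom.source + t[:, None] * (p - geom.source)
    rel = q - geom.det_center
    return np.column_stack([rel @ geom.u_axis, rel @ geom.v_axis])


def project_point(point, geom: ProjectionGeometry) -> np.ndarray:
    return project_points(point, geom)[0]


def project_landmarks(
    landmarks: LandmarkSet3D,
    pose: RigidPose,
    geom: ProjectionGeometry,
    arcs: Mapping[str, np.ndarray] | None = None,
) -> LandmarkSet2D | tuple[LandmarkSet2D, dict[str, np.ndarray]]:
    """Apply a specimen pose and project 3D landmarks onto the detector.

    ``arcs`` may carry named 3D point sets (N, 3) to project alongside; the
    sagittal arc samples are stored as (x, y, 0) plane points and are
    rotated with the same pose.
    """
    R = pose.matrix()
    o = geom.frame_origin

    def transform(pts3):
        return (np.atleast_2d(pts3) - o) @ R.T + o

    names = landmarks.names()
    uv = project_points(transform(landmarks.array(names)), geom)
    out = LandmarkSet2D({n: uv[i] for i, n in enumerate(names)})
    if arcs is None:
        return out
    arcs2d = {}
    for key, pts in arcs.items():
        pts = np.asarray(pts, float)
        if pts.shape[1] == 2:  # sagittal-plane samples at z = 0
            pts = np.column_stack([pts, np.zeros(len(pts))])
        arcs2d[key] = project_points(transform(pts), geom)
    return out, arcs2d


def _pixel_centers_world(geom: ProjectionGeometry) -> np.ndarray:
    nu, nv = geom.image_size
    u = (np.arange(nu) - (nu - 1) / 2) * geom.pixel_spacing
    v = (np.arange(nv) - (nv - 1) / 2) * geom.pixel_spacing
    U, V = np.meshgrid(u, v, indexing="ij")
    return (geom.det_center[None, None, :]
            + U[..., None] * geom.u_axis[None, None, :]
            + V[..., None] * geom.v_axis[None, None, :])


def cast_drr(
    volume: VoxelVolume,
    pose: RigidPose | None,
    geom: ProjectionGeometry,
    step: float | None = None,
) -> DRRImage:
    """Render a DRR by fixed-step ray casting with trilinear interpolation.

    The specimen pose (argument composed with any pose already carried by
    the volume) is honoured by rotating sample positions into the volume's
    unrotated grid — the grid itself is never resampled.  Samples outside
    the volume contribute zero.  The default step is half the smallest
    voxel dimension.
    """
    if step is None:
        step = 0.5 * float(np.min(volume.spacing))
    if step <= 0:
        raise ValueError("ray-casting step must be > 0")
    pose = pose or RigidPose()

    # compose: total rotation applied to the anatomy
    if volume.pose is not None and not volume.pose.is_identity:
        R_total = pose.compose(volume.pose).as_matrix()
        center = volume.rot_center if volume.rot_center is not None else geom.frame_origin
    else:
        R_total = pose.matrix()
        center = geom.frame_origin
    center = np.asarray(center, float)

    # transform source and pixel targets into the volume's grid space
    Rinv = R_total.T

    def to_grid_space(p):
        return (p - center) @ R_total + center  # inverse rotation of anatomy motion

    src = to_grid_space(geom.source)
    targets = to_grid_space(_pixel_centers_world(geom).reshape(-1, 3))
    dirs = targets - src
    lengths = np.linalg.norm(dirs, axis=1)
    dirs /= lengths[:, None]

    # ray/AABB intersection (slab method) against the voxel-centre bounds
    lo, hi = volume.world_bounds()
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - src[None, :]) / dirs
        t2 = (hi[None, :] - src[None, :]) / dirs
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = tmax > np.maximum(tmin, 0)
    if not hit.any():
        raise ValueError("volume does not intersect the source-detector frustum")
    t0 = float(np.min(tmin[hit]))
    t_end = float(np.max(tmax[hit]))

    accum = np.zeros(len(dirs), dtype=np.float64)
    inv_sp = 1.0 / volume.spacing
    n_steps = int(math.ceil((t_end - t0) / step))
    vals = volume.values.astype(np.float32, copy=False)
    t_in = np.where(hit, tmin, np.inf)
    t_out = np.where(hit, tmax, -np.inf)
    for k in range(n_steps):
        lo_k = t0 + k * step
        # weight each sample by its step's overlap with the ray's
        # inside-volume interval and sample at the overlap midpoint, so
        # partial steps at the volume boundary integrate correctly
        seg_lo = np.maximum(lo_k, t_in)
        seg_hi = np.minimum(lo_k + step, t_out)
        w = np.clip(seg_hi - seg_lo, 0.0, step) / step
        active = w > 0
        if not active.any():
            continue
        t_mid = 0.5 * (seg_lo[active] + seg_hi[active])
        pos = src[None, :] + t_mid[:, None] * dirs[active]
        coords = (pos - volume.origin) * inv_sp
        accum[active] += w[active] * ndimage.map_coordinates(
            vals, coords.T, order=1, mode="constant", cval=0.0)
    pixels = (accum * step).reshape(geom.image_size)
    return DRRImage(pixels, geom.pixel_spacing, geom.view, pose, geom)


def write_drr(img: DRRImage, path_base) -> list:
    """Write a DRR as lossless float TIFF plus a windowed 16-bit PNG."""
    from pathlib import Path

    import imageio.v3 as iio
    import tifffile

    base = Path(path_base)
    out = []
    tif = base.with_suffix(".tiff")
    tifffile.imwrite(str(tif), np.asarray(img.pixels, dtype=np.float32))
    out.append(tif)
    mx = float(img.pixels.max())
    win = (np.clip(img.pixels / mx if mx > 0 else img.pixels, 0, 1) * 65535).astype(np.uint16)
    png = base.with_suffix(".png")
    iio.imwrite(str(png), win.T[::-1])  # v up, u right
    out.append(png)
    return out
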