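"""Core geometric types for radiographic ankle-morphometry simulation.

World coordinates are millimetres in the anatomical frame of the specimen:

* ``X`` — anteroposterior axis (+X anterior),
* ``Y`` — superoinferior axis (+Y superior, the tibial long axis),
* ``Z`` — mediolateral axis (+Z medial for a right ankle),

with the origin at the geometric centre of the talus.  The frame mimics the
fixation-frame definition used for cadaver imaging: the axes come from the
specimen fixture (they are *not* re-derived from bone geometry), only the
origin is taken from the talus itself.

Voxel volumes are node-centred: the world position of voxel ``(i, j, k)`` is
``origin + spacing * (i, j, k)`` with array axis 0 = X, 1 = Y, 2 = Z.  Rigid
poses applied to a volume are carried as metadata and honoured at ray-casting
time; the scalar grid itself is never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import trimesh
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "VoxelVolume",
    "SurfaceMesh",
    "AnatomicalFrame",
    "RigidPose",
    "LandmarkSet3D",
    "compute_anatomical_frame",
    "apply_pose",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_frame",
    "write_frame",
    "read_pose",
    "write_pose",
]


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point contains non-finite values: {a}")
    return a


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelVolume:
    """A 3D attenuation grid with physical spacing and origin (mm).

    ``pose``/``rot_center`` carry a rigid rotation applied to the anatomy:
    sample positions are mapped through the inverse rotation at DRR time so
    no interpolation loss is accumulated by re-gridding.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    pose: "RigidPose | None" = None
    rot_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation values must be finite")
        if np.any(self.values < 0):
            raise ValueError("attenuation values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_bounds(self) -> np.ndarray:
        """(2, 3) array of [min, max] voxel-centre world coordinates."""
        lo = self.origin
        hi = self.origin + self.spacing * (np.array(self.shape) - 1)
        return np.stack([lo, hi])


@dataclass
class SurfaceMesh:
    """Triangulated bone surface in world millimetres."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.as_trimesh().vertex_normals)

    def drop_degenerate_faces(self) -> "SurfaceMesh":
        tm = self.as_trimesh()
        keep = tm.area_faces > 1e-12
        return SurfaceMesh(self.vertices, self.faces[keep], self.label)


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame (axes are rows)."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    def __post_init__(self) -> None:
        self.origin = _as_point(self.origin)
        self.axis_x = _as_point(self.axis_x)
        self.axis_y = _as_point(self.axis_y)
        self.axis_z = _as_point(self.axis_z)
        R = self.rotation_matrix()
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("frame must be right-handed (axis_z = axis_x x axis_y)")

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1))

    def rotation_matrix(self) -> np.ndarray:
        """Rows are the frame axes expressed in world coordinates."""
        return np.stack([self.axis_x, self.axis_y, self.axis_z])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World -> frame coordinates."""
        return (np.atleast_2d(points) - self.origin) @ self.rotation_matrix().T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation_matrix() + self.origin

    def rotate_directions(self, vecs: np.ndarray) -> np.ndarray:
        """World direction vectors -> frame components (no translation)."""
        return np.atleast_2d(vecs) @ self.rotation_matrix().T


@dataclass(frozen=True)
class RigidPose:
    """Rotation angles (degrees) about the anatomical axes, about the frame
    origin.  Composition is extrinsic about the fixed anatomical axes in the
    order X -> Y -> Z; for the <= 6 degree perturbations studied here order
    effects are second-order, but the convention is fixed."""

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.theta_x, self.theta_y, self.theta_z):
            if not np.isfinite(v):
                raise ValueError("pose angles must be finite")

    @property
    def is_identity(self) -> bool:
        return self.theta_x == self.theta_y == self.theta_z == 0.0

    def rotation(self) -> Rotation:
        return Rotation.from_euler(
            "xyz", [self.theta_x, self.theta_y, self.theta_z], degrees=True
        )

    def matrix(self) -> np.ndarray:
        return self.rotation().as_matrix()

    def compose(self, other: "RigidPose") -> Rotation:
        """Rotation of ``self`` applied after ``other``."""
        return self.rotation() * other.rotation()

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.theta_x, self.theta_y, self.theta_z)


class LandmarkSet3D:
    """Named anatomical points (mm).  Sagittal-plane landmarks (A, B, C, D, V
    and the central trochlea points) are stored at Z = 0 by convention, since
    the parameters they define live in the sagittal plane."""

    def __init__(self, points: Mapping[str, Iterable[float]] | None = None):
        self.points: dict[str, np.ndarray] = {}
        if points:
            for k, v in points.items():
                self[k] = v

    def __setitem__(self, name: str, value) -> None:
        self.points[name] = _as_point(value)

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

    def names(self) -> list[str]:
        return list(self.points)

    def array(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.names()
        return np.stack([self[n] for n in names])

    def update(self, other: "LandmarkSet3D") -> "LandmarkSet3D":
        self.points.update(other.points)
        return self

    def copy(self) -> "LandmarkSet3D":
        return LandmarkSet3D(self.points)

    def transformed(self, fn) -> "LandmarkSet3D":
        return LandmarkSet3D({k: fn(v.reshape(1, 3)).reshape(3) for k, v in self.points.items()})

    def to_json_dict(self) -> dict:
        return {k: v.tolist() for k, v in self.points.items()}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_anatomical_frame(talus_mesh: SurfaceMesh) -> AnatomicalFrame:
    """Anatomical frame with the origin at the geometric centre of the talus.

    The centre is the area-weighted centroid of the talar surface (a proxy
    for the geometric centre, recorded as such in output metadata).  The axes
    follow the fixture convention: they are the world axes the specimen was
    constructed/aligned in, not axes derived from the bone shape.
    """
    if len(talus_mesh.faces) == 0 or len(talus_mesh.vertices) == 0:
        raise ValueError("cannot compute an anatomical frame from an empty mesh")
    tm = talus_mesh.as_trimesh()
    areas = tm.area_faces
    if areas.sum() <= 0:
        raise ValueError("talus mesh has zero surface area")
    centroid = (tm.triangles_center * areas[:, None]).sum(axis=0) / areas.sum()
    return AnatomicalFrame(centroid, (1, 0, 0), (0, 1, 0), (0, 0, 1))


def apply_pose(model, pose: RigidPose, frame: AnatomicalFrame):
    """Rigidly rotate ``model`` by ``pose`` about the anatomical-frame origin.

    Meshes and landmark sets are rotated analytically.  Volumes carry the
    rotation as metadata (composed with any rotation already present) and are
    only ever sampled through it during DRR casting.
    """
    R = pose.matrix()
    o = frame.origin

    def rot(pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - o) @ R.T + o

    if isinstance(model, SurfaceMesh):
        if pose.is_identity:
            return SurfaceMesh(model.vertices.copy(), model.faces.copy(), model.label)
        return SurfaceMesh(rot(model.vertices), model.faces.copy(), model.label)
    if isinstance(model, LandmarkSet3D):
        if pose.is_identity:
            return model.copy()
        return model.transformed(rot)
    if isinstance(model, VoxelVolume):
        if model.pose is None or model.pose.is_identity:
            new_rot = pose.rotation()
        else:
            new_rot = pose.compose(model.pose)
        ang = new_rot.as_euler("xyz", degrees=True)
        return replace(
            model,
            pose=RigidPose(*ang),
            rot_center=o.copy(),
        )
    raise TypeError(f"cannot apply a pose to {type(model).__name__}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as MHD/MHA (SimpleITK) or NIfTI (nibabel)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name} (use .mhd/.mha/.nii/.nii.gz)")
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as e:  # pragma: no cover - message passthrough
            raise ValueError(f"malformed MHD volume {path}: {e}") from e
        values = np.asarray(sitk.GetArrayFromImage(img)).T
        return VoxelVolume(values, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        return VoxelVolume(np.asarray(img.dataobj, dtype=np.float32), spacing, affine[:3, 3])
    raise ValueError(f"unsupported volume format: {path.name}")


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise ValueError(f"unsupported mesh format: {path.suffix} (use .stl or .ply)")
    mesh.as_trimesh().export(str(path))
    return path


def read_mesh(path: str | Path, label: str = "") -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as e:
        raise ValueError(f"malformed mesh file {path}: {e}") from e
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label or path.stem)


def write_frame(frame: AnatomicalFrame, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "origin": frame.origin.tolist(),
        "axis_X": frame.axis_x.tolist(),
        "axis_Y": frame.axis_y.tolist(),
        "axis_Z": frame.axis_z.tolist(),
        "origin_definition": "area-weighted talar surface centroid",
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def read_frame(path: str | Path) -> AnatomicalFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame file not found: {path}")
    data = yaml.safe_load(path.read_text())
    try:
        return AnatomicalFrame(data["origin"], data["axis_X"], data["axis_Y"], data["axis_Z"])
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed frame file {path}: missing field {e}") from e


def write_pose(pose: RigidPose, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            {"theta_X": pose.theta_x, "theta_Y": pose.theta_y, "theta_Z": pose.theta_z,
             "units": "degrees", "order": "extrinsic X->Y->Z"},
            sort_keys=False,
        )
    )
    return path


def read_pose(path: str | Path) -> RigidPose:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pose file not found: {path}")
    data = yaml.safe_load(path.read_text())
    try:
        return RigidPose(data["theta_X"], data["theta_Y"], data["theta_Z"])
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed pose file {path}: missing field {e}") from e
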