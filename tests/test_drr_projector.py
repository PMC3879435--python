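import math

import numpy as np
import pytest
from scipy import ndimage

from anklemorph.bone_models import AnatomicalFrame, LandmarkSet3D, RigidPose, VoxelVolume
from anklemorph.drr_projector import (
    SID_MM,
    ProjectionGeometry,
    cast_drr,
    make_standard_geometry,
    project_landmarks,
    project_point,
    project_points,
)


def simple_geometry(pixel_spacing=1.0, image_size=(21, 21)):
    """Detector in the z = -100 plane, source on the +z axis at SID."""
    return ProjectionGeometry(
        source=(0, 0, SID_MM - 100), det_center=(0, 0, -100),
        u_axis=(1, 0, 0), v_axis=(0, 1, 0),
        pixel_spacing=pixel_spacing, image_size=image_size, view="ML",
    )


def trilinear_oracle(vol: VoxelVolume, pts: np.ndarray) -> np.ndarray:
    """Independent gather-based trilinear interpolation (zero outside)."""
    idx = (pts - vol.origin) / vol.spacing
    i0 = np.floor(idx).astype(int)
    f = idx - i0
    out = np.zeros(len(pts))
    shape = np.array(vol.shape)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corner = i0 + [dx, dy, dz]
                ok = np.all((corner >= 0) & (corner < shape), axis=1)
                w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                     * np.where(dy, f[:, 1], 1 - f[:, 1])
                     * np.where(dz, f[:, 2], 1 - f[:, 2]))
                c = corner[ok]
                out[ok] += w[ok] * vol.values[c[:, 0], c[:, 1], c[:, 2]]
    return out


def brute_force_ray(vol, src, target, step):
    """Fine-step line integral with the oracle interpolator."""
    d = target - src
    L = np.linalg.norm(d)
    d = d / L
    lo, hi = vol.world_bounds()
    with np.errstate(divide="ignore"):
        t1 = (lo - src) / d
        t2 = (hi - src) / d
    tmin = np.nanmax(np.minimum(t1, t2))
    tmax = np.nanmin(np.maximum(t1, t2))
    if tmax <= tmin:
        return 0.0
    ts = np.arange(tmin, tmax, step) + step / 2
    pts = src[None, :] + ts[:, None] * d[None, :]
    return float(trilinear_oracle(vol, pts).sum() * step)


@pytest.fixture(scope="module")
def smooth_volume():
    rng = np.random.default_rng(99)
    vals = rng.random((24, 24, 24))
    vals = ndimage.gaussian_filter(vals, 2.0).astype(np.float32)
    return VoxelVolume(vals, (1.3, 1.3, 1.2), (-15.0, -14.0, -14.0))


class TestProjection:
    def test_point_on_detector_projects_to_itself(self):
        geom = simple_geometry()
        uv = project_point((7.0, -3.0, -100.0), geom)
        assert uv == pytest.approx((7.0, -3.0), abs=1e-12)

    def test_similar_triangles_offset(self):
        # 10 mm off the principal ray at 100 mm depth -> 10 * 1000/900
        geom = simple_geometry()
        uv = project_point((10.0, 0.0, 0.0), geom)
        assert uv[0] == pytest.approx(10 * SID_MM / (SID_MM - 100), abs=1e-9)

    @pytest.mark.parametrize("depth", [0.0, 35.0, 100.0])
    def test_magnification_law(self, depth):
        geom = simple_geometry()
        z = -100.0 + depth
        p = np.array([[0.0, 0.0, z], [28.41, 0.0, z], [0.0, 11.3, z]])
        uv = project_points(p, geom)
        mag = SID_MM / (SID_MM - depth)
        assert np.linalg.norm(uv[1] - uv[0]) / 28.41 == pytest.approx(mag, rel=2e-3)
        assert np.linalg.norm(uv[2] - uv[0]) / 11.3 == pytest.approx(mag, rel=2e-3)

    def test_point_behind_source_rejected(self):
        geom = simple_geometry()
        with pytest.raises(ValueError, match="behind"):
            project_point((0.0, 0.0, SID_MM + 50), geom)

    def test_collinearity_is_preserved(self):
        geom = simple_geometry()
        p0 = np.array([3.0, -2.0, -40.0])
        d = np.array([1.0, 2.0, 0.5])
        pts = p0 + np.outer([0.0, 0.7, 1.9], d)
        uv = project_points(pts, geom)
        v01 = uv[1] - uv[0]
        v02 = uv[2] - uv[0]
        cross = v01[0] * v02[1] - v01[1] * v02[0]
        assert abs(cross) < 1e-9


class TestStandardGeometry:
    def test_ml_contact_and_sid(self, default_phantom):
        geom = make_standard_geometry("ML", default_phantom.meshes, default_phantom.frame)
        z_lat = min(m.vertices[:, 2].min() for m in default_phantom.meshes.values())
        assert geom.det_center[2] == pytest.approx(z_lat, abs=1e-9)
        assert geom.source[2] == pytest.approx(z_lat + SID_MM, abs=1e-9)
        # principal ray passes through the medial malleolus
        tib = default_phantom.tibia.vertices
        tibmed = tib[np.argmax(tib[:, 2])]
        assert np.linalg.norm(geom.det_center[:2] - tibmed[:2]) < 1e-9
        assert geom.sid == pytest.approx(SID_MM)

    def test_ap_principal_ray_through_intermalleolar_midpoint(self, default_phantom):
        geom = make_standard_geometry("AP", default_phantom.meshes, default_phantom.frame)
        tib = default_phantom.tibia.vertices
        fib = default_phantom.fibula.vertices
        mid = 0.5 * (tib[np.argmax(tib[:, 2])] + fib[np.argmin(fib[:, 2])])
        # distance from the midpoint to the principal axis (source->det_center)
        axis = geom.det_center - geom.source
        axis = axis / np.linalg.norm(axis)
        rel = mid - geom.source
        dist = np.linalg.norm(rel - (rel @ axis) * axis)
        assert dist < 1e-9

    def test_invalid_view_rejected(self, default_phantom):
        with pytest.raises(ValueError, match="view"):
            make_standard_geometry("XY", default_phantom.meshes, default_phantom.frame)

    def test_left_side_flips_source(self, default_phantom):
        from anklemorph.phantom_cohort import PhantomSpec, generate_phantom
        lph = generate_phantom(PhantomSpec(side="left"))
        geom_r = make_standard_geometry("ML", default_phantom.meshes,
                                        default_phantom.frame, side="right")
        geom_l = make_standard_geometry("ML", lph.meshes, lph.frame, side="left")
        assert geom_r.source[2] > 0 > geom_l.source[2]


class TestRayCasting:
    def _cube_volume(self):
        vals = np.zeros((61, 61, 61), np.float32)
        vals[6:56, 6:56, 6:56] = 1.0  # 50 mm attenuating cube
        return VoxelVolume(vals, (1, 1, 1), (-30.0, -30.0, -30.0))

    def test_face_on_path_length(self):
        img = cast_drr(self._cube_volume(), None, simple_geometry(), step=0.4)
        assert img.pixels[10, 10] == pytest.approx(50.0, rel=0.01)

    def test_oblique_path_length(self):
        img = cast_drr(self._cube_volume(), RigidPose(0, 10, 0), simple_geometry(), step=0.4)
        assert img.pixels[10, 10] == pytest.approx(50 / math.cos(math.radians(10)), rel=0.01)

    def test_background_rays_are_zero(self):
        geom = simple_geometry(pixel_spacing=10.0)
        img = cast_drr(self._cube_volume(), None, geom, step=0.5)
        assert img.pixels[0, 0] == 0.0

    def test_nonpositive_step_rejected(self, smooth_volume):
        with pytest.raises(ValueError):
            cast_drr(smooth_volume, None, simple_geometry(), step=0.0)

    def test_determinism(self, smooth_volume):
        geom = simple_geometry(pixel_spacing=2.0, image_size=(11, 11))
        a = cast_drr(smooth_volume, RigidPose(3, 2, 1), geom)
        b = cast_drr(smooth_volume, RigidPose(3, 2, 1), geom)
        assert np.array_equal(a.pixels, b.pixels)

    def test_matches_brute_force_oracle(self, smooth_volume, rng):
        """Trilinear ray caster vs an independent fine-step integrator on
        100 random rays: agreement within 0.5% relative."""
        geom = simple_geometry(pixel_spacing=1.2, image_size=(31, 31))
        step = 0.5 * float(min(smooth_volume.spacing))
        img = cast_drr(smooth_volume, None, geom, step=step)
        src = geom.source
        nu, nv = geom.image_size
        picks = rng.integers(5, 26, size=(100, 2))
        fine = 0.1 * float(min(smooth_volume.spacing))
        for iu, iv in picks:
            u = (iu - (nu - 1) / 2) * geom.pixel_spacing
            v = (iv - (nv - 1) / 2) * geom.pixel_spacing
            target = geom.det_center + u * geom.u_axis + v * geom.v_axis
            ref = brute_force_ray(smooth_volume, src, np.asarray(target), fine)
            got = float(img.pixels[iu, iv])
            assert got == pytest.approx(ref, rel=5e-3, abs=1e-3)


class TestLandmarkProjection:
    def test_identity_pose_detector_plane_landmark_unchanged(self):
        geom = simple_geometry()
        lm = LandmarkSet3D({"p": (4.0, 5.0, -100.0)})
        out = project_landmarks(lm, RigidPose(), geom)
        assert out["p"] == pytest.approx((4.0, 5.0), abs=1e-12)

    def test_in_plane_rotation_rotates_projections(self):
        """Rotating the specimen about the projection axis rotates the 2D
        landmarks about the principal point by the same angle (equal depth)."""
        geom = simple_geometry()
        z = -40.0
        pts = {"a": (10.0, 0.0, z), "b": (0.0, 15.0, z), "c": (-5.0, -5.0, z)}
        lm = LandmarkSet3D(pts)
        th = 7.0
        out0 = project_landmarks(lm, RigidPose(), geom)
        out1 = project_landmarks(lm, RigidPose(0, 0, th), geom)
        c, s = math.cos(math.radians(th)), math.sin(math.radians(th))
        R = np.array([[c, -s], [s, c]])
        for n in pts:
            assert np.allclose(out1[n], R @ out0[n], atol=1e-9), n
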