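"""Pose-perturbation experiments: systematic sensitivity sweep and the
randomized repeatability protocol.

The sensitivity protocol rotates the specimen away from the standard pose
by up to 6 degrees at 1-degree intervals in both directions about each
anatomical axis — 12 perturbed poses per axis plus the shared standard
pose, i.e. 37 poses per view — and reports each parameter's percent change
relative to its own standard-pose 2D value.  The repeatability protocol
draws random pose errors (uniform per rotation component within a bound)
and feeds the resulting measurement matrices to ICC(3,k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bone_models import RigidPose
from .drr_projector import ProjectionGeometry, make_standard_geometry, project_landmarks
from .morphometry2d import View2D, measure_view_2d
from .morphometry3d import (
    FRONTAL_PARAMETERS,
    SAGITTAL_PARAMETERS,
    MorphometryConfig,
    measure_bones_3d,
)
from .phantom_cohort import AnklePhantom

__all__ = [
    "AXES",
    "SWEEP_ANGLES",
    "PoseSet",
    "SensitivityTable",
    "TrendResult",
    "sweep_poses",
    "sensitivity_sweep",
    "trend_test",
    "random_pose_set",
    "repeatability_experiment",
    "measure_posed_view",
]

AXES = ("X", "Y", "Z")
#: the systematic perturbation magnitudes (degrees)
SWEEP_ANGLES = tuple(range(-6, 7))


def _axis_pose(axis: str, angle: float) -> RigidPose:
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    return RigidPose(**{f"theta_{axis.lower()}": float(angle)})


def sweep_poses() -> list[tuple[str, float, RigidPose]]:
    """All (axis, angle, pose) combinations of the systematic protocol.

    The standard pose appears once (tagged axis ``"0"``), giving the
    protocol's 37 distinct poses per view.
    """
    out: list[tuple[str, float, RigidPose]] = [("0", 0.0, RigidPose())]
    for axis in AXES:
        for ang in SWEEP_ANGLES:
            if ang == 0:
                continue
            out.append((axis, float(ang), _axis_pose(axis, ang)))
    return out


def measure_posed_view(
    landmarks,
    arcs,
    pose: RigidPose,
    geom: ProjectionGeometry,
    variant: str = "c",
) -> dict[str, float]:
    """2D parameter values for one specimen pose on one view."""
    lm2d, arcs2d = project_landmarks(landmarks, pose, geom, arcs)
    profile = measure_view_2d(geom.view, View2D(lm2d, arcs2d), variant=variant)
    return profile.values


@dataclass
class TrendResult:
    kind: str            # "linear" | "quadratic" | "none"
    p_linear: float
    p_quadratic: float
    b_linear: float
    b_quadratic: float

    @property
    def symbol(self) -> str:
        return {"linear": "lin", "quadratic": "quad", "none": "-"}[self.kind]


def trend_test(angles, errors, alpha: float = 0.05) -> TrendResult:
    """Polynomial trend of percent error against perturbation angle.

    Fits ``error = b1*angle + b2*angle**2`` (no intercept: zero perturbation
    gives zero error by definition) and classifies the trend by coefficient
    significance at ``alpha``.
    """
    angles = np.asarray(angles, float)
    errors = np.asarray(errors, float)
    ok = np.isfinite(errors)
    angles, errors = angles[ok], errors[ok]
    if len(angles) < 5:
        raise ValueError("trend test needs at least 5 angle points")
    if np.allclose(errors, 0.0):
        return TrendResult("none", 1.0, 1.0, 0.0, 0.0)
    X = np.column_stack([angles, angles**2])
    fit = sm.OLS(errors, X).fit()
    p1, p2 = float(fit.pvalues[0]), float(fit.pvalues[1])
    b1, b2 = float(fit.params[0]), float(fit.params[1])
    # perfect polynomial data leaves ~zero residual variance: decide by the
    # coefficient's numerically-significant contribution instead of p-values
    scale = float(np.abs(errors).max())
    if abs(b1) * np.abs(angles).max() < 1e-9 * scale:
        p1 = 1.0
    if abs(b2) * (angles**2).max() < 1e-9 * scale:
        p2 = 1.0
    if np.isnan(p1):
        p1 = 0.0 if abs(b1) * np.abs(angles).max() >= 1e-9 * scale else 1.0
    if np.isnan(p2):
        p2 = 0.0 if abs(b2) * (angles**2).max() >= 1e-9 * scale else 1.0
    if p2 < alpha:
        kind = "quadratic"
    elif p1 < alpha:
        kind = "linear"
    else:
        kind = "none"
    return TrendResult(kind, p1, p2, b1, b2)


@dataclass
class SensitivityTable:
    """Long-format sensitivity results plus per-parameter trend tests."""

    view: str
    data: pd.DataFrame          # axis, angle_deg, parameter, value, pct_error, abs_error
    trends: pd.DataFrame        # parameter, axis, trend, p_linear, p_quadratic
    n_poses: int = 0

    def wide(self, angles=(-6, -3, 3, 6)) -> pd.DataFrame:
        """Percent errors in the conventional sensitivity-table layout:
        parameter rows, (axis, angle) columns plus a trend column."""
        rows = {}
        for param, g in self.data.groupby("parameter", sort=False):
            row = {}
            for axis in AXES:
                ga = g[g.axis == axis].set_index("angle_deg")
                for a in angles:
                    row[(axis, f"{a:+d}")] = ga.pct_error.get(float(a), np.nan)
                tr = self.trends.query("parameter == @param and axis == @axis")
                row[(axis, "trend")] = tr.trend.iloc[0] if len(tr) else "-"
            rows[param] = row
        return pd.DataFrame(rows).T


def sensitivity_sweep(
    phantom: AnklePhantom,
    view: str,
    config: MorphometryConfig | None = None,
    use_truth_landmarks: bool = False,
    geometry: ProjectionGeometry | None = None,
) -> SensitivityTable:
    """Systematic +-6 degree, 1-degree-interval sensitivity analysis.

    Measures the view's 2D parameters at every pose of the systematic
    protocol and reports percent error against the standard-pose 2D value
    (plus the absolute error, which is better conditioned for parameters
    with near-zero baselines such as the frontal talar tilt).  Parameters
    undefined at a pose (landmark outside the frustum) are recorded as
    missing, never extrapolated.
    """
    cfg = config or MorphometryConfig()
    if use_truth_landmarks:
        lm, arcs = phantom.truth_landmarks, phantom.truth_arcs
    else:
        _, lm, arcs = measure_bones_3d(phantom.tibia, phantom.fibula,
                                       phantom.talus, phantom.frame, cfg)
    geom = geometry or make_standard_geometry(view, phantom.meshes, phantom.frame,
                                              side=cfg.side)
    params = SAGITTAL_PARAMETERS if view.upper() == "ML" else FRONTAL_PARAMETERS
    poses = sweep_poses()
    records = []
    baseline: dict[str, float] = {}
    for axis, ang, pose in poses:
        try:
            values = measure_posed_view(lm, arcs, pose, geom, cfg.variant)
        except ValueError:
            values = {}
        if axis == "0":
            baseline = values
        records.append((axis, ang, values))
    rows = []
    for axis, ang, values in records:
        use_axes = AXES if axis == "0" else (axis,)
        for ax in use_axes:
            for p in params:
                v = values.get(p, np.nan)
                v0 = baseline.get(p, np.nan)
                defined = np.isfinite(v) and np.isfinite(v0) and v0 != 0.0
                pct = 100.0 * (v - v0) / v0 if defined else np.nan
                rows.append({"axis": ax, "angle_deg": float(ang), "parameter": p,
                             "value": v, "pct_error": pct, "abs_error": v - v0})
    data = pd.DataFrame(rows).sort_values(["parameter", "axis", "angle_deg"],
                                          kind="stable").reset_index(drop=True)
    trows = []
    for (p, ax), g in data.groupby(["parameter", "axis"], sort=False):
        g = g.dropna(subset=["pct_error"])
        if len(g) >= 5:
            tr = trend_test(g.angle_deg.values, g.pct_error.values)
            trows.append({"parameter": p, "axis": ax, "trend": tr.kind,
                          "p_linear": tr.p_linear, "p_quadratic": tr.p_quadratic,
                          "b_linear": tr.b_linear, "b_quadratic": tr.b_quadratic})
        else:
            trows.append({"parameter": p, "axis": ax, "trend": "-",
                          "p_linear": np.nan, "p_quadratic": np.nan,
                          "b_linear": np.nan, "b_quadratic": np.nan})
    return SensitivityTable(view.upper(), data, pd.DataFrame(trows), n_poses=len(poses))


@dataclass
class PoseSet:
    """Random specimen poses for the repeatability/correction protocols."""

    poses: list[RigidPose]
    bound_deg: float
    seed: int
    distribution: str = "uniform"

    def __iter__(self):
        return iter(self.poses)

    def __len__(self) -> int:
        return len(self.poses)


def random_pose_set(bound_deg: float, n: int = 10, seed: int = 0) -> PoseSet:
    """Draw ``n`` poses with each rotation component uniform in [-bound, bound]."""
    if bound_deg <= 0:
        raise ValueError("bound_deg must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-bound_deg, bound_deg, size=(n, 3))
    return PoseSet([RigidPose(*a) for a in angles], bound_deg, seed)


def repeatability_experiment(
    phantoms: list[AnklePhantom],
    view: str,
    bound_deg: float = 6.0,
    n_poses: int = 10,
    seed: int = 0,
    config: MorphometryConfig | None = None,
    share_poses: bool = False,
) -> dict[str, pd.DataFrame]:
    """Measure every specimen under ``n_poses`` random poses on one view.

    Each specimen gets its own independent random pose set (the protocol's
    default); ``share_poses`` reuses one set for all specimens.  Returns one
    (specimen x pose) measurement matrix per parameter, ready for ICC(3,k).
    Missing measurements stay NaN; the ICC computation reports how many
    complete rows it used.
    """
    if len(phantoms) < 2:
        raise ValueError("repeatability needs a cohort of >= 2 specimens")
    cfg = config or MorphometryConfig()
    params = SAGITTAL_PARAMETERS if view.upper() == "ML" else FRONTAL_PARAMETERS
    per_param: dict[str, np.ndarray] = {p: np.full((len(phantoms), n_poses), np.nan)
                                        for p in params}
    for i, ph in enumerate(phantoms):
        _, lm, arcs = measure_bones_3d(ph.tibia, ph.fibula, ph.talus, ph.frame, cfg)
        geom = make_standard_geometry(view, ph.meshes, ph.frame, side=cfg.side)
        pose_set = random_pose_set(bound_deg, n_poses,
                                   seed=seed if share_poses else seed + 1000 * i)
        for j, pose in enumerate(pose_set):
            try:
                values = measure_posed_view(lm, arcs, pose, geom, cfg.variant)
            except ValueError:
                continue
            for p in params:
                per_param[p][i, j] = values.get(p, np.nan)
    cols = [f"pose{j}" for j in range(n_poses)]
    idx = [f"specimen{i}" for i in range(len(phantoms))]
    return {p: pd.DataFrame(m, index=idx, columns=cols) for p, m in per_param.items()}
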