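"""Lower-leg pose resolution and the trajectory-error metric.

Given a foot design and one stance instance (GRF, CoP, knee moment), the
engine finds the orientation of the foot+shank assembly that satisfies the
ground-contact constraints, and from it the lower-leg pose: knee position
``(x_knee, y_knee)`` and shank angle ``theta_shank``.

Contact model (no-slip, point application of the GRF):

* **flat contact** (mid-stance): the load is applied at the material sole
  station under the CoP; the foot orientation ``phi`` is found such that the
  deformed sole is tangent to the ground at that point, which is then
  placed at ``(cop_x, 0)`` in the lab.
* **line contact** (heel strike / toe-off): the CoP is stationary at the
  heel or toe extremity and tangency no longer constrains the orientation;
  ``phi`` is instead found by matching the reference knee moment: the root
  of ``r(phi) = moment_implied_by_pose(phi) - knee_moment_ref``.

The "knee" is a virtual point rigidly attached to the shank adapter,
vertically above the ankle (C1 origin) at the lower-leg length from the
ground when the foot is flat and unloaded.  Foot rotations ``phi`` are
counterclockwise positive; with +x the walking direction this makes
``theta_shank = -phi`` (knee anterior of the ankle for negative ``phi``).

The trajectory error aggregates pose deviations over N stance instances:

    LLTE = sqrt( (1/N) * sum_n [ ((x_n^model - x_n^ref)/x_bar)^2
                               + ((y_n^model - y_n^ref)/y_bar)^2
                               + ((th_n^model - th_n^ref)/th_bar)^2 ] )

with each normalizer the mean absolute value of the corresponding reference
variable over the instances considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .gait import (FLAT_CONTACT, HEEL_LINE_CONTACT, TOE_LINE_CONTACT, LoadCase,
                   ReferenceGait, UserCharacteristics, knee_moment_from_kinetics,
                   reference_pose_at)
from .parametrization import (FootDesign, FrameMesh, evaluate_geometry,
                              mesh_geometry)
from .solver import (DeformedState, Material, PointLoad, SolverError,
                     SolverOptions, max_stress, recover_stresses,
                     solve_quasi_static)

__all__ = [
    "LowerLegPose",
    "TrajectoryResult",
    "LLTEValue",
    "PoseSolverOptions",
    "FootModel",
    "solve_flat_contact_pose",
    "solve_line_contact_pose",
    "compute_trajectory",
    "compute_llte",
    "predict_trajectory_from_measured",
    "trajectory_rmse",
    "InfeasiblePoseError",
]


class InfeasiblePoseError(RuntimeError):
    pass


@dataclass(frozen=True)
class LowerLegPose:
    """Lab-frame lower-leg pose at one stance instance."""

    knee_x: float  # m
    knee_y: float  # m
    theta_shank: float  # deg, + knee anterior of ankle
    phi: float  # deg, foot orientation vs lab (CCW +)
    regime: str


@dataclass
class TrajectoryResult:
    """Model lower-leg poses over an ordered list of stance instances."""

    percents: np.ndarray  # (N,)
    poses: list[LowerLegPose | None]  # None for failed frames
    converged: np.ndarray  # (N,) bool
    max_stress: np.ndarray  # (N,) Pa (nan for failed frames)

    @property
    def n_frames(self) -> int:
        return int(self.percents.size)

    def pose_arrays(self):
        """(knee_x, knee_y, theta_shank) arrays with NaN at failed frames."""
        kx = np.array([p.knee_x if p else np.nan for p in self.poses])
        ky = np.array([p.knee_y if p else np.nan for p in self.poses])
        th = np.array([p.theta_shank if p else np.nan for p in self.poses])
        return kx, ky, th


@dataclass(frozen=True)
class LLTEValue:
    """The scalar trajectory error plus its per-frame decomposition."""

    value: float
    per_frame_terms: np.ndarray  # (N, 3) normalized squared deviations
    n_frames: int
    normalizers: tuple[float, float, float]  # x_bar, y_bar, theta_bar

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class PoseSolverOptions:
    """Numerical controls for the orientation search."""

    phi_bracket_deg: float = 45.0  # search half-width around the warm start
    grid_step_deg: float = 1.0  # bracketing scan resolution
    xtol: float = 1e-10  # rad, root-finder tolerance
    moment_tol: float = 0.1  # N*m, line-contact residual acceptance
    fea: SolverOptions = field(default_factory=SolverOptions)


def _rot(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


class FootModel:
    """A meshed foot design bound to a user, ready for pose solving.

    Caches the mesh and exposes the foot-frame <-> lab conversions shared by
    the pose solvers.  ``cop_x`` inputs are heel-relative; the foot frame
    has the ankle (C1) at the origin, so stations are shifted by the ankle
    fraction of foot length.
    """

    def __init__(self, design: FootDesign, mat: Material,
                 user: UserCharacteristics, n_elements: int = 300,
                 width: float = 0.060, samples_per_segment: int = 80):
        self.design = design
        self.material = mat
        self.user = user
        self.geometry = evaluate_geometry(design, samples_per_segment)
        self.mesh: FrameMesh = mesh_geometry(self.geometry, n_elements, width)
        self.knee_foot = np.array([0.0, user.lower_leg_length - design.h_ank])

    def cop_to_foot(self, cop_x_lab: float) -> float:
        return cop_x_lab - self.design.ankle_fraction * self.design.L_foot

    def solve_fea(self, force_lab: np.ndarray, phi: float, node: int,
                  opts: PoseSolverOptions) -> DeformedState:
        force_foot = _rot(-phi) @ np.asarray(force_lab, dtype=float)
        load = PointLoad(force=force_foot, node=node)
        return solve_quasi_static(self.mesh, self.material, load, opts.fea)

    def sole_node_for(self, cop_x_lab: float) -> int:
        return self.mesh.sole.station_node(self.cop_to_foot(cop_x_lab))

    def deformed_sole_point(self, state: DeformedState, node: int) -> np.ndarray:
        """Bottom-fiber position of a sole node in the deformed foot frame."""
        k = self.mesh.sole.sole_index_of(node)
        off = self.mesh.sole.offset_vec[k]
        th = state.displacements[node, 2]
        return (self.mesh.nodes[node] + state.displacements[node, :2]
                + _rot(th) @ off)

    def sole_tangent_angle(self, state: DeformedState, node: int) -> float:
        """Deformed sole tangent angle (foot frame, heel->toe direction)."""
        k = self.mesh.sole.sole_index_of(node)
        return float(self.mesh.sole.tangent_angle[k]
                     + state.displacements[node, 2])

    def pose_from_contact(self, phi: float, contact_foot: np.ndarray,
                          cop_x_lab: float, regime: str) -> LowerLegPose:
        knee = _rot(phi) @ (self.knee_foot - contact_foot) + np.array([cop_x_lab, 0.0])
        return LowerLegPose(knee_x=float(knee[0]), knee_y=float(knee[1]),
                            theta_shank=float(-np.degrees(phi)),
                            phi=float(np.degrees(phi)), regime=regime)


def _bracket_root(f, warm: float, opts: PoseSolverOptions):
    """Find a sign-change bracket for ``f`` near ``warm`` (radians)."""
    half = np.radians(opts.phi_bracket_deg)
    step = np.radians(opts.grid_step_deg)
    # cheap first attempt: a narrow window around the warm start
    for width in (4 * step, 16 * step, half):
        a, b = warm - width, warm + width
        fa, fb = f(a), f(b)
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb <= 0:
            return a, b
    # full grid scan
    grid = np.arange(warm - half, warm + half + step / 2, step)
    vals = np.array([f(g) for g in grid])
    sign = np.sign(vals)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if flips.size == 0:
        raise InfeasiblePoseError("no orientation root within the search bracket")
    # branch nearest the warm start
    k = flips[np.argmin(np.abs(grid[flips] - warm))]
    return grid[k], grid[k + 1]


def solve_flat_contact_pose(model: FootModel, case: LoadCase,
                            warm_start_phi: float = 0.0,
                            opts: PoseSolverOptions | None = None) -> LowerLegPose:
    """Resolve the flat-contact (mid-stance) pose.

    Finds ``phi`` such that the deformed sole tangent at the loaded material
    point is ground-parallel; that point is then placed at the CoP.
    """
    if case.regime != FLAT_CONTACT:
        raise ValueError("case regime must be flat_contact")
    opts = opts or PoseSolverOptions()
    node = model.sole_node_for(case.cop_x)
    cache: dict[float, DeformedState] = {}

    def residual(phi: float) -> float:
        state = cache.get(phi)
        if state is None:
            state = model.solve_fea(case.grf, phi, node, opts)
            cache[phi] = state
            if not state.converged:
                raise InfeasiblePoseError("FEA did not converge during pose search")
        return model.sole_tangent_angle(state, node) + phi

    a, b = _bracket_root(residual, np.radians(warm_start_phi), opts)
    phi = brentq(residual, a, b, xtol=opts.xtol)
    state = cache.get(phi) or model.solve_fea(case.grf, phi, node, opts)
    contact = model.deformed_sole_point(state, node)
    return model.pose_from_contact(phi, contact, case.cop_x, FLAT_CONTACT)


def solve_line_contact_pose(model: FootModel, case: LoadCase,
                            warm_start_phi: float = 0.0,
                            opts: PoseSolverOptions | None = None) -> LowerLegPose:
    """Resolve a heel-strike or toe-off pose by matching the knee moment.

    With the foot pivoting about the stationary CoP near the heel or toe
    end of the sole, tangency no longer applies; the orientation is the
    root of the scalar residual
    ``implied_knee_moment(phi) - reference_moment``.  The pivot is the sole
    material point at the CoP station (the CoP saturates short of the
    geometric toe: the effective foot length is below the physical one).
    """
    if case.regime not in (HEEL_LINE_CONTACT, TOE_LINE_CONTACT):
        raise ValueError("case regime must be heel or toe line contact")
    opts = opts or PoseSolverOptions()
    node = model.sole_node_for(case.cop_x)
    cache: dict[float, LowerLegPose] = {}

    def pose_at(phi: float) -> LowerLegPose:
        pose = cache.get(phi)
        if pose is None:
            state = model.solve_fea(case.grf, phi, node, opts)
            if not state.converged:
                raise InfeasiblePoseError("FEA did not converge during pose search")
            contact = model.deformed_sole_point(state, node)
            pose = model.pose_from_contact(phi, contact, case.cop_x, case.regime)
            cache[phi] = pose
        return pose

    def residual(phi: float) -> float:
        p = pose_at(phi)
        return knee_moment_from_kinetics((p.knee_x, p.knee_y), case.grf,
                                         case.cop_x) - case.knee_moment

    a, b = _bracket_root(residual, np.radians(warm_start_phi), opts)
    phi = brentq(residual, a, b, xtol=opts.xtol)
    if abs(residual(phi)) > opts.moment_tol:
        raise InfeasiblePoseError("moment residual above tolerance at returned root")
    return pose_at(phi)


def compute_trajectory(design: FootDesign, mat: Material, cases: list[LoadCase],
                       user: UserCharacteristics,
                       n_elements: int = 300, width: float = 0.060,
                       opts: PoseSolverOptions | None = None,
                       model: FootModel | None = None) -> TrajectoryResult:
    """Solve the lower-leg pose for every stance instance of ``cases``.

    Frames are solved in stance order with the previous orientation as the
    warm start; any infeasible frame is flagged rather than raised so that
    optimizers can penalize it.  The peak combined stress is recorded per
    frame.
    """
    opts = opts or PoseSolverOptions()
    if model is None:
        model = FootModel(design, mat, user, n_elements=n_elements, width=width)
    order = np.argsort([c.stance_percent for c in cases])
    cases_sorted = [cases[k] for k in order]

    poses: list[LowerLegPose | None] = []
    stresses: list[float] = []
    flags: list[bool] = []
    warm = 0.0
    for case in cases_sorted:
        try:
            if case.regime == FLAT_CONTACT:
                pose = solve_flat_contact_pose(model, case, warm, opts)
            else:
                pose = solve_line_contact_pose(model, case, warm, opts)
            node = model.sole_node_for(case.cop_x)
            state = model.solve_fea(case.grf, np.radians(pose.phi), node, opts)
            stress = max_stress(recover_stresses(model.mesh, mat, state))
            poses.append(pose)
            stresses.append(stress)
            flags.append(True)
            warm = pose.phi
        except (InfeasiblePoseError, SolverError):
            poses.append(None)
            stresses.append(np.nan)
            flags.append(False)

    return TrajectoryResult(
        percents=np.array([c.stance_percent for c in cases_sorted]),
        poses=poses,
        converged=np.array(flags, dtype=bool),
        max_stress=np.array(stresses),
    )


def compute_llte(model_traj: TrajectoryResult, ref: ReferenceGait,
                 percents=None, failed_frame_penalty: float = 10.0) -> LLTEValue:
    """Evaluate the trajectory-error metric of a solved trajectory.

    Normalizers are the mean absolute values of the reference knee
    coordinates and shank angle over the instances considered.  Each failed
    frame contributes a squared penalty term (default ``10**2``) so that
    infeasible designs still rank.
    """
    if percents is None:
        percents = model_traj.percents
    percents = np.asarray(percents, dtype=float)
    refpose = reference_pose_at(ref, percents)
    xbar = float(np.mean(np.abs(refpose["knee_x"])))
    ybar = float(np.mean(np.abs(refpose["knee_y"])))
    tbar = float(np.mean(np.abs(refpose["theta_shank"])))
    if min(xbar, ybar, tbar) < 1e-12:
        raise ValueError("degenerate reference: zero normalizer")
    kx, ky, th = model_traj.pose_arrays()
    terms = np.empty((percents.size, 3))
    for n in range(percents.size):
        if model_traj.converged[n]:
            terms[n] = [
                ((kx[n] - refpose["knee_x"][n]) / xbar) ** 2,
                ((ky[n] - refpose["knee_y"][n]) / ybar) ** 2,
                ((th[n] - refpose["theta_shank"][n]) / tbar) ** 2,
            ]
        else:
            terms[n] = failed_frame_penalty**2
    value = float(np.sqrt(np.mean(np.sum(terms, axis=1))))
    return LLTEValue(value=value, per_frame_terms=terms,
                     n_frames=int(percents.size), normalizers=(xbar, ybar, tbar))


def predict_trajectory_from_measured(design: FootDesign, mat: Material,
                                     measured_cases: list[LoadCase],
                                     user: UserCharacteristics,
                                     **kwargs) -> TrajectoryResult:
    """Predict the lower-leg trajectory from *measured* kinetics.

    Same machinery as :func:`compute_trajectory` but driven by per-step
    measured GRF/CoP/knee-moment series (already resampled to the stance
    percents of interest) instead of the published reference — the
    constitutive-model validation route.
    """
    return compute_trajectory(design, mat, measured_cases, user, **kwargs)


def trajectory_rmse(predicted: TrajectoryResult,
                    measured: dict[str, np.ndarray]) -> dict[str, float]:
    """Mean absolute error per pose channel between prediction and measurement.

    ``measured`` maps ``knee_x``/``knee_y`` (m) and ``theta_shank`` (deg) to
    arrays aligned with the predicted frames.
    """
    kx, ky, th = predicted.pose_arrays()
    out = {}
    for name, arr in (("knee_x", kx), ("knee_y", ky), ("theta_shank", th)):
        diff = arr - np.asarray(measured[name], dtype=float)
        out[name] = float(np.nanmean(np.abs(diff)))
    return out
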