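"""Closed-form reduced foot model for instance-selection studies.

Deciding how many stance instances the trajectory-error evaluation needs is
done — as in the framework's own development — on a *simple analytical*
foot model rather than the full finite-element one, so that optimizing over
every stance percent stays cheap.

The reduced model is a rigid ankle block with two uniform cantilever
beams: the forefoot beam extends toward the toe and the heel beam toward
the heel, both rooted at the ankle station and resting on the ground line
``y = -h_ank`` when unloaded.  Under a vertical contact force ``F`` applied
at lever ``l`` from the root, Euler-Bernoulli theory gives the sole slope
and deflection at the contact point in closed form:

    psi = F l^2 / (2 E_f I),    delta = F l^3 / (3 E_f I),

which feed exactly the same contact-pose construction as the full model
(flat contact: tangency at the CoP; line contact: knee-moment matching
about the stationary CoP station).  The two free design variables are
dimensionless
thickness scales of the forefoot and heel beams (bending stiffness scales
with thickness cubed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .engine import InfeasiblePoseError, LLTEValue, LowerLegPose, TrajectoryResult, compute_llte
from .gait import (FLAT_CONTACT, HEEL_LINE_CONTACT, TOE_LINE_CONTACT, LoadCase,
                   ReferenceGait, knee_moment_from_kinetics, resample_stance)
from .solver import NYLON_66, Material

__all__ = ["AnalyticFoot", "analytic_trajectory", "analytic_llte"]


def _rot(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class AnalyticFoot:
    """Two-beam closed-form foot: forefoot and heel thickness scales free."""

    keel_scale: float = 1.0  # forefoot-beam thickness multiplier
    heel_scale: float = 1.0  # heel-beam thickness multiplier
    keel_base_thickness: float = 0.008  # m, at scale 1
    heel_base_thickness: float = 0.0055  # m, at scale 1
    width: float = 0.060  # m
    h_ank: float = 0.080  # m
    foot_length: float = 0.26  # m
    lower_leg_length: float = 0.50  # m
    ankle_fraction: float = 0.25
    material: Material = NYLON_66

    def __post_init__(self) -> None:
        if self.keel_scale <= 0 or self.heel_scale <= 0:
            raise ValueError("thickness scales must be positive")

    def _EI(self, base: float, scale: float) -> float:
        t = base * scale
        return self.material.flexural_modulus * self.width * t**3 / 12.0

    @property
    def EI_forefoot(self) -> float:
        return self._EI(self.keel_base_thickness, self.keel_scale)

    @property
    def EI_heel(self) -> float:
        return self._EI(self.heel_base_thickness, self.heel_scale)

    @property
    def toe_x(self) -> float:
        return (1.0 - self.ankle_fraction) * self.foot_length

    @property
    def heel_x(self) -> float:
        return -self.ankle_fraction * self.foot_length

    @property
    def knee_foot(self) -> np.ndarray:
        return np.array([0.0, self.lower_leg_length - self.h_ank])

    def cop_to_foot(self, cop_x_lab: float) -> float:
        return cop_x_lab - self.ankle_fraction * self.foot_length

    # -- beam response -------------------------------------------------

    def _beam_response(self, x_foot: float, f_transverse: float):
        """Sole slope (rad, CCW) and vertical deflection at station ``x_foot``."""
        if x_foot >= 0.0:
            lever, EI, sgn = x_foot, self.EI_forefoot, +1.0
        else:
            lever, EI, sgn = -x_foot, self.EI_heel, -1.0
        psi = sgn * f_transverse * lever**2 / (2.0 * EI)
        delta = f_transverse * lever**3 / (3.0 * EI)
        return psi, delta

    # -- pose solvers ---------------------------------------------------

    def flat_pose(self, case: LoadCase) -> LowerLegPose:
        """Tangency pose under flat contact (closed form in the load frame).

        The transverse beam load is the foot-frame normal force; since the
        resulting rotations are small the residual ``psi(phi) + phi = 0`` is
        solved with a couple of fixed-point sweeps, which converges to
        machine precision for physical stiffnesses.
        """
        x_c = self.cop_to_foot(case.cop_x)
        phi = 0.0
        for _ in range(60):
            f_foot = _rot(-phi) @ case.grf
            psi, _ = self._beam_response(x_c, f_foot[1])
            phi_new = -psi
            if abs(phi_new - phi) < 1e-14:
                phi = phi_new
                break
            phi = phi_new
        f_foot = _rot(-phi) @ case.grf
        psi, delta = self._beam_response(x_c, f_foot[1])
        contact = np.array([x_c, -self.h_ank + delta])
        knee = _rot(phi) @ (self.knee_foot - contact) + np.array([case.cop_x, 0.0])
        return LowerLegPose(knee_x=float(knee[0]), knee_y=float(knee[1]),
                            theta_shank=float(-np.degrees(phi)),
                            phi=float(np.degrees(phi)), regime=FLAT_CONTACT)

    def line_pose(self, case: LoadCase, warm_phi_deg: float = 0.0) -> LowerLegPose:
        """Heel/toe line-contact pose from knee-moment matching.

        The pivot is the sole station under the (stationary) CoP.
        """
        x_t = self.cop_to_foot(case.cop_x)

        def pose_at(phi: float) -> LowerLegPose:
            f_foot = _rot(-phi) @ case.grf
            _, delta = self._beam_response(x_t, f_foot[1])
            tip = np.array([x_t, -self.h_ank + delta])
            knee = _rot(phi) @ (self.knee_foot - tip) + np.array([case.cop_x, 0.0])
            return LowerLegPose(knee_x=float(knee[0]), knee_y=float(knee[1]),
                                theta_shank=float(-np.degrees(phi)),
                                phi=float(np.degrees(phi)), regime=case.regime)

        def residual(phi: float) -> float:
            p = pose_at(phi)
            return knee_moment_from_kinetics((p.knee_x, p.knee_y), case.grf,
                                             case.cop_x) - case.knee_moment

        warm = np.radians(warm_phi_deg)
        for width in (0.1, 0.3, 0.8, 1.4):
            a, b = warm - width, warm + width
            if residual(a) * residual(b) <= 0:
                phi = brentq(residual, a, b, xtol=1e-12)
                return pose_at(phi)
        raise InfeasiblePoseError("no orientation matches the reference knee moment")


def analytic_trajectory(foot: AnalyticFoot, cases: list[LoadCase]) -> TrajectoryResult:
    """Solve every stance instance with the closed-form model."""
    order = np.argsort([c.stance_percent for c in cases])
    cases_sorted = [cases[k] for k in order]
    poses: list[LowerLegPose | None] = []
    flags = []
    warm = 0.0
    for case in cases_sorted:
        try:
            if case.regime == FLAT_CONTACT:
                pose = foot.flat_pose(case)
            else:
                pose = foot.line_pose(case, warm)
            poses.append(pose)
            flags.append(True)
            warm = pose.phi
        except InfeasiblePoseError:
            poses.append(None)
            flags.append(False)
    return TrajectoryResult(
        percents=np.array([c.stance_percent for c in cases_sorted]),
        poses=poses,
        converged=np.array(flags, dtype=bool),
        max_stress=np.full(len(cases_sorted), np.nan),
    )


def analytic_llte(foot: AnalyticFoot, ref: ReferenceGait, percents) -> LLTEValue:
    """Trajectory error of the reduced model over ``percents`` of stance."""
    cases = resample_stance(ref, percents)
    traj = analytic_trajectory(foot, cases)
    return compute_llte(traj, ref, traj.percents)
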