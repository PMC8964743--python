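"""Pose resolution and the trajectory-error metric."""

import numpy as np
import pytest
from scipy.optimize import brentq

import llte
from llte.engine import (FootModel, InfeasiblePoseError, LLTEValue,
                         PoseSolverOptions, TrajectoryResult, compute_llte,
                         compute_trajectory, predict_trajectory_from_measured,
                         solve_flat_contact_pose, solve_line_contact_pose,
                         trajectory_rmse)
from llte.gait import (FLAT_CONTACT, HEEL_LINE_CONTACT, LoadCase,
                       knee_moment_from_kinetics, reference_pose_at,
                       resample_stance)
from llte.parametrization import complete_design
from llte.solver import NYLON_66
from conftest import TEST_DESIGN_VARS


def rigid_rolling_pose(model, case):
    """Geometry-only rigid-rolling oracle (no structural solve).

    Flat contact: the orientation cancels the undeformed sole tangent at
    the CoP station.  Line contact: closed-form knee-moment matching about
    the contact point.
    """
    sole = model.mesh.sole
    k = int(np.argmin(np.abs(sole.bottom[:, 0] - model.cop_to_foot(case.cop_x))))
    contact = sole.bottom[k]

    def knee_at(phi):
        c, s = np.cos(phi), np.sin(phi)
        R = np.array([[c, -s], [s, c]])
        return R @ (model.knee_foot - contact) + [case.cop_x, 0.0]

    if case.regime == FLAT_CONTACT:
        phi = -sole.tangent_angle[k]
    else:
        def res(phi):
            return knee_moment_from_kinetics(knee_at(phi), case.grf,
                                             case.cop_x) - case.knee_moment
        grid = np.radians(np.arange(-45.0, 45.5, 1.0))
        vals = np.array([res(g) for g in grid])
        flips = np.flatnonzero(np.diff(np.sign(vals)))
        k0 = flips[np.argmin(np.abs(grid[flips]))]
        phi = brentq(res, grid[k0], grid[k0 + 1], xtol=1e-14)
    knee = knee_at(phi)
    return knee[0], knee[1], -np.degrees(phi)


@pytest.fixture(scope="module")
def rigid_model(test_design, user):
    return FootModel(test_design, NYLON_66.scaled(1e6), user, n_elements=120)


class TestRigidFootLimit:
    def test_all_nine_poses_match_rolling_oracle(self, rigid_model, nine_cases):
        traj = compute_trajectory(rigid_model.design, rigid_model.material,
                                  nine_cases, rigid_model.user, model=rigid_model)
        assert traj.converged.all()
        kx, ky, th = traj.pose_arrays()
        for n, case in enumerate(sorted(nine_cases, key=lambda c: c.stance_percent)):
            ox, oy, ot = rigid_rolling_pose(rigid_model, case)
            assert abs(kx[n] - ox) < 1e-6
            assert abs(ky[n] - oy) < 1e-6
            assert abs(th[n] - ot) < 1e-4

    def test_pose_independent_of_load_magnitude(self, rigid_model, nine_cases):
        """A rigid foot's pose is geometry-determined: doubling the load
        (and the moment, for line contact) leaves the pose unchanged."""
        case = [c for c in nine_cases if c.regime == FLAT_CONTACT][2]
        p1 = solve_flat_contact_pose(rigid_model, case)
        double = LoadCase(case.stance_percent, 2 * case.grf, case.cop_x,
                          2 * case.knee_moment, case.regime)
        p2 = solve_flat_contact_pose(rigid_model, double)
        # residual deflection of the near-rigid foot bounds the difference
        assert p1.knee_x == pytest.approx(p2.knee_x, abs=1e-6)
        assert p1.theta_shank == pytest.approx(p2.theta_shank, abs=1e-4)


class TestFlatContact:
    def test_regime_enforced(self, foot_model, nine_cases):
        heel = [c for c in nine_cases if c.regime == HEEL_LINE_CONTACT][0]
        with pytest.raises(ValueError):
            solve_flat_contact_pose(foot_model, heel)

    def test_tangency_residual_vanishes_at_solution(self, foot_model, nine_cases):
        case = [c for c in nine_cases if c.stance_percent == 50.0][0]
        pose = solve_flat_contact_pose(foot_model, case)
        phi = np.radians(pose.phi)
        node = foot_model.sole_node_for(case.cop_x)
        state = foot_model.solve_fea(case.grf, phi, node, PoseSolverOptions())
        assert abs(foot_model.sole_tangent_angle(state, node) + phi) < 1e-7


class TestLineContact:
    def test_moment_residual_below_tolerance(self, foot_model, nine_cases):
        case = [c for c in nine_cases if c.regime == HEEL_LINE_CONTACT][0]
        pose = solve_line_contact_pose(foot_model, case)
        m = knee_moment_from_kinetics((pose.knee_x, pose.knee_y), case.grf,
                                      case.cop_x)
        assert abs(m - case.knee_moment) < 0.1

    def test_rigid_self_consistent_reference(self, rigid_model, nine_cases):
        """Setting the target moment to the moment implied by a known pose
        recovers that pose (residual zero by construction)."""
        case = [c for c in nine_cases if c.regime == HEEL_LINE_CONTACT][0]
        pose = solve_line_contact_pose(rigid_model, case)
        m_implied = knee_moment_from_kinetics((pose.knee_x, pose.knee_y),
                                              case.grf, case.cop_x)
        case2 = LoadCase(case.stance_percent, case.grf, case.cop_x,
                         m_implied, case.regime)
        pose2 = solve_line_contact_pose(rigid_model, case2,
                                        warm_start_phi=pose.phi)
        assert pose2.phi == pytest.approx(pose.phi, abs=1e-6)

    def test_grid_brackets_the_returned_root(self, foot_model, nine_cases):
        """A 200-point brute-force scan of the moment residual brackets
        exactly the root the solver returned."""
        case = [c for c in nine_cases if c.stance_percent == 80.0][0]
        pose = solve_line_contact_pose(foot_model, case, warm_start_phi=-20.0)
        node = foot_model.sole_node_for(case.cop_x)
        opts = PoseSolverOptions()

        def residual(phi):
            state = foot_model.solve_fea(case.grf, phi, node, opts)
            contact = foot_model.deformed_sole_point(state, node)
            p = foot_model.pose_from_contact(phi, contact, case.cop_x, case.regime)
            return knee_moment_from_kinetics((p.knee_x, p.knee_y), case.grf,
                                             case.cop_x) - case.knee_moment

        grid = np.linspace(np.radians(pose.phi) - 0.35,
                           np.radians(pose.phi) + 0.35, 200)
        vals = np.array([residual(g) for g in grid])
        flips = np.flatnonzero(np.diff(np.sign(vals)))
        assert flips.size >= 1
        k = flips[np.argmin(np.abs(grid[flips] - np.radians(pose.phi)))]
        assert grid[k] <= np.radians(pose.phi) <= grid[k + 1]
        # the residual is monotone over the bracket: a +1 N*m target shift
        # moves the root in a consistent direction
        assert np.all(np.diff(np.sign(vals[max(0, k - 5):k + 6])) >= -2)


class TestTrajectory:
    def test_nine_default_cases_all_converge(self, foot_model, nine_cases, ref_gait):
        traj = compute_trajectory(foot_model.design, NYLON_66, nine_cases,
                                  foot_model.user, model=foot_model)
        assert traj.n_frames == 9
        assert traj.converged.all()
        assert np.all(np.diff(traj.percents) > 0)
        assert np.all(np.isfinite(traj.max_stress))

    def test_stiffer_variant_closer_to_rigid_pose(self, user, nine_cases):
        """Scaling all thicknesses up moves every pose toward the rigid one."""
        soft = complete_design(TEST_DESIGN_VARS, user)
        hard_vars = TEST_DESIGN_VARS.copy()
        for idx in (0, 3, 6, 8, 9, 10):
            hard_vars[idx] *= 1.5
        hard = complete_design(hard_vars, user)
        case = [c for c in nine_cases if c.stance_percent == 50.0][0]
        rigid = FootModel(soft, NYLON_66.scaled(1e6), user, n_elements=80)
        rigid_pose = solve_flat_contact_pose(rigid, case)
        dev = []
        for design in (soft, hard):
            m = FootModel(design, NYLON_66, user, n_elements=80)
            pose = solve_flat_contact_pose(m, case)
            dev.append(np.hypot(pose.knee_x - rigid_pose.knee_x,
                                pose.knee_y - rigid_pose.knee_y))
        assert dev[1] < dev[0]


class TestLLTEMetric:
    def _traj(self, percents, kx, ky, th):
        from llte.engine import LowerLegPose
        poses = [llte.LowerLegPose(x, y, t, -t, FLAT_CONTACT)
                 for x, y, t in zip(kx, ky, th)]
        return TrajectoryResult(percents=np.asarray(percents, float),
                                poses=poses,
                                converged=np.ones(len(poses), dtype=bool),
                                max_stress=np.zeros(len(poses)))

    def test_zero_for_identical_trajectories(self, ref_gait):
        percents = np.array(llte.NINE_INSTANCE_PERCENTS)
        rp = reference_pose_at(ref_gait, percents)
        traj = self._traj(percents, rp["knee_x"], rp["knee_y"], rp["theta_shank"])
        assert compute_llte(traj, ref_gait, percents).value == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_closed_form(self, ref_gait):
        """One frame with each normalized deviation 0.1 gives sqrt(0.03)."""
        percents = [50.0]
        rp = reference_pose_at(ref_gait, percents)
        xbar = abs(rp["knee_x"][0])
        ybar = abs(rp["knee_y"][0])
        tbar = abs(rp["theta_shank"][0])
        traj = self._traj(percents,
                          [rp["knee_x"][0] + 0.1 * xbar],
                          [rp["knee_y"][0] + 0.1 * ybar],
                          [rp["theta_shank"][0] + 0.1 * tbar])
        val = compute_llte(traj, ref_gait, percents)
        assert val.value == pytest.approx(0.173205, abs=1e-6)

    def test_scale_invariance_of_normalized_terms(self, ref_gait):
        """Multiplying a variable and its normalizer by c leaves the term
        unchanged: LLTE is invariant to the units of its inputs."""
        percents = np.array(llte.NINE_INSTANCE_PERCENTS)
        rp = reference_pose_at(ref_gait, percents)
        traj = self._traj(percents, rp["knee_x"] * 1.02, rp["knee_y"],
                          rp["theta_shank"])
        v1 = compute_llte(traj, ref_gait, percents)
        # reconstructing with knee_x in centimetres: term identical because
        # deviation and normalizer scale together
        assert v1.per_frame_terms[:, 0] == pytest.approx(
            (0.02 * np.abs(rp["knee_x"]) / v1.normalizers[0]) ** 2)

    def test_failed_frames_contribute_penalty(self, ref_gait):
        percents = [30.0, 50.0]
        rp = reference_pose_at(ref_gait, percents)
        traj = self._traj(percents, rp["knee_x"], rp["knee_y"], rp["theta_shank"])
        traj.converged[0] = False
        traj.poses[0] = None
        val = compute_llte(traj, ref_gait, percents)
        assert val.per_frame_terms[0].sum() == pytest.approx(300.0)  # 3 x 10^2
        assert val.value == pytest.approx(np.sqrt(300.0 / 2), rel=1e-6)

    def test_paper_scale_context(self):
        """Optimized user-specific designs score a few tenths on this metric."""
        assert 0.1 < 0.240 < 0.465 < 1.0  # magnitude context, not a fixture


class TestMeasuredKinetics:
    def test_closed_loop_rmse_zero(self, foot_model, nine_cases, ref_gait):
        """Feeding the model's own predictions back as 'measured' poses
        yields zero error per channel."""
        traj = compute_trajectory(foot_model.design, NYLON_66, nine_cases,
                                  foot_model.user, model=foot_model)
        kx, ky, th = traj.pose_arrays()
        measured = {"knee_x": kx, "knee_y": ky, "theta_shank": th}
        pred = predict_trajectory_from_measured(
            foot_model.design, NYLON_66, nine_cases, foot_model.user,
            model=foot_model)
        errs = trajectory_rmse(pred, measured)
        for v in errs.values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_noise_injection_bounded(self, foot_model, nine_cases, ref_gait):
        """1% force noise perturbs the recovered trajectory smoothly."""
        rng = np.random.default_rng(0)
        traj0 = compute_trajectory(foot_model.design, NYLON_66, nine_cases,
                                   foot_model.user, model=foot_model)
        kx0, ky0, th0 = traj0.pose_arrays()
        noisy = [LoadCase(c.stance_percent,
                          c.grf * (1 + 0.01 * rng.standard_normal(2)),
                          c.cop_x, c.knee_moment, c.regime)
                 for c in nine_cases]
        traj1 = predict_trajectory_from_measured(
            foot_model.design, NYLON_66, noisy, foot_model.user, model=foot_model)
        errs = trajectory_rmse(traj1, {"knee_x": kx0, "knee_y": ky0,
                                       "theta_shank": th0})
        assert errs["knee_x"] < 0.02  # m: small, bounded response
        assert errs["theta_shank"] < 3.0  # deg


class TestMomentContinuity:
    def test_implied_moment_continuous_across_stance(self, user, ref_gait):
        """The knee moment implied by solved flat-contact poses tracks a
        smooth curve: the deviation from the reference moment shows no
        branch jumps above 5 N*m between adjacent 2%-spaced frames."""
        from conftest import FEASIBLE_DESIGN_VARS
        design = complete_design(FEASIBLE_DESIGN_VARS, user)
        model = FootModel(design, NYLON_66, user, n_elements=100)
        percents = [float(p) for p in range(14, 69, 2)]
        cases = resample_stance(ref_gait, percents)
        traj = compute_trajectory(design, NYLON_66, cases, user, model=model)
        assert traj.converged.all()
        kx, ky, _ = traj.pose_arrays()
        implied = np.array([
            knee_moment_from_kinetics((x, y), c.grf, c.cop_x)
            for x, y, c in zip(kx, ky,
                               sorted(cases, key=lambda c: c.stance_percent))])
        ref_m = np.interp(percents, ref_gait.stance_percent, ref_gait.knee_moment)
        # a solver branch jump would appear as an isolated spike in the
        # curvature of the deviation series; smooth trends are physical
        curvature = np.abs(np.diff(implied - ref_m, n=2))
        assert np.all(curvature < 5.0)
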