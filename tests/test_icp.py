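import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpsa.icp import (
    DegenerateGeometryError,
    ICPParams,
    RigidTransform,
    correspond,
    eq_cost,
    icp_superimpose,
    init_candidates,
    principal_axes,
    select_init,
    solve_symmetric_step,
)
from gpsa.mesh_io import Surface
from gpsa.synth import BumpSpec, PopulationSpec, make_population


def random_rigid(seed, max_angle_deg=30.0, max_trans=0.5):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.radians(max_angle_deg))
    rot = Rotation.from_rotvec(axis * angle).as_matrix()
    return RigidTransform(rot, rng.uniform(-max_trans, max_trans, 3))


class TestRigidTransform:
    def test_group_laws(self):
        t = random_rigid(4)
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(ident.translation, 0.0, atol=1e-9)

    def test_compose_order(self):
        a, b = random_rigid(1), random_rigid(2)
        pts = np.random.default_rng(0).normal(size=(5, 3))
        np.testing.assert_allclose(
            a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12
        )

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestPrincipalAxes:
    def test_ellipsoid_axes_ordered(self, ellipsoid):
        _, axes = principal_axes(ellipsoid.points)
        assert abs(axes[0] @ [1, 0, 0]) > np.cos(np.radians(5))
        assert abs(axes[1] @ [0, 1, 0]) > np.cos(np.radians(5))
        # right-handed frame
        assert np.isclose(np.dot(np.cross(axes[0], axes[1]), axes[2]), 1.0)

    def test_equivariance_under_rotation(self, bumped_ellipsoid):
        rot = Rotation.from_euler("xyz", [15, 25, -40], degrees=True).as_matrix()
        _, axes = principal_axes(bumped_ellipsoid.points)
        _, axes_r = principal_axes(bumped_ellipsoid.points @ rot.T)
        for a, ar in zip(axes[:2], axes_r[:2]):
            assert abs(np.dot(rot @ a, ar)) > 1.0 - 1e-6

    def test_collinear_rejected(self):
        pts = np.outer(np.linspace(0, 1, 20), [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            principal_axes(pts)

    def test_isotropic_cloud_still_returns_valid_frame(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(500, 3))
        _, axes = principal_axes(pts)
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(axes), 1.0, atol=1e-9)


class TestInitialization:
    def test_identity_candidate_for_equal_surfaces(self, bumped_ellipsoid):
        cands = init_candidates(bumped_ellipsoid, bumped_ellipsoid)
        best = min(
            cands,
            key=lambda c: np.abs(c.rotation - np.eye(3)).max()
            + np.abs(c.translation).max(),
        )
        assert np.allclose(best.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(best.translation, 0.0, atol=1e-9)

    def test_all_candidates_proper_rotations(self, asymmetric_pair):
        a, b = asymmetric_pair
        cands = init_candidates(a, b)
        assert len(cands) == 4
        for c in cands:
            assert np.isclose(np.linalg.det(c.rotation), 1.0, atol=1e-9)

    def test_known_rotation_recovered(self, bumped_ellipsoid):
        truth = random_rigid(7, max_angle_deg=25.0)
        moved = truth.apply_to(bumped_ellipsoid)
        cands = init_candidates(bumped_ellipsoid, moved)
        errs = [
            truth.inverse().compose(c).angle_deg for c in cands
        ]
        assert min(errs) < 1e-6

    def test_select_init_prefers_symmetry_breaking_pose(self, bumped_ellipsoid):
        truth = random_rigid(11, max_angle_deg=20.0)
        moved = truth.apply_to(bumped_ellipsoid)
        chosen = select_init(
            bumped_ellipsoid, moved, init_candidates(bumped_ellipsoid, moved)
        )
        assert truth.inverse().compose(chosen).angle_deg < 1e-6

    def test_single_candidate_returned_unconditionally(self, bumped_ellipsoid):
        only = random_rigid(3)
        assert (
            select_init(bumped_ellipsoid, bumped_ellipsoid, [only]) is only
        )


class TestSymmetricStep:
    def test_identity_pairings_give_identity_step(self, bumped_ellipsoid):
        corr = correspond(bumped_ellipsoid, bumped_ellipsoid)
        step = solve_symmetric_step(bumped_ellipsoid, bumped_ellipsoid, corr)
        assert step.angle_deg < 1e-10
        assert np.linalg.norm(step.translation) < 1e-12

    def test_pure_translation_recovered(self, bumped_ellipsoid):
        delta = np.array([0.08, -0.03, 0.05])
        moved = RigidTransform(np.eye(3), delta).apply_to(bumped_ellipsoid)
        corr = correspond(bumped_ellipsoid, moved)
        step = solve_symmetric_step(bumped_ellipsoid, moved, corr)
        assert step.angle_deg < 0.05
        np.testing.assert_allclose(step.translation, delta, atol=5e-3)
        # exact cost decreases
        after = step.apply_to(bumped_ellipsoid)
        assert eq_cost(after, moved, correspond(after, moved)) < eq_cost(
            bumped_ellipsoid, moved, corr
        )

    def test_small_rotation_recovered(self, bumped_ellipsoid):
        rot = Rotation.from_euler("z", 2, degrees=True).as_matrix()
        moved = RigidTransform(rot, np.zeros(3)).apply_to(bumped_ellipsoid)
        corr = correspond(bumped_ellipsoid, moved)
        step = solve_symmetric_step(bumped_ellipsoid, moved, corr)
        residual = np.degrees(
            np.linalg.norm(
                Rotation.from_matrix(rot.T @ step.rotation).as_rotvec()
            )
        )
        assert residual < 0.05

    def test_parallel_normals_degenerate(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 1, (40, 2)), np.zeros(40)])
        plane = Surface(points=pts)
        corr = correspond(plane, plane)
        with pytest.raises(DegenerateGeometryError):
            solve_symmetric_step(plane, plane, corr)


class TestSuperimposition:
    @pytest.mark.parametrize("seed", range(10))
    def test_rigid_motion_recovered(self, bumped_ellipsoid, seed):
        """A rigidly moved exact copy is recovered to ground truth."""
        truth = random_rigid(100 + seed, max_angle_deg=30.0)
        moved = truth.apply_to(bumped_ellipsoid)
        res = icp_superimpose(bumped_ellipsoid, moved)
        err = truth.inverse().compose(res.transform)
        diag = bumped_ellipsoid.bounding_box_diagonal
        assert err.angle_deg < 0.1
        assert np.linalg.norm(err.translation) < 1e-3 * diag
        assert res.psm < 1e-6 * diag

    def test_already_aligned_terminates_immediately(self, bumped_ellipsoid):
        res = icp_superimpose(
            bumped_ellipsoid, bumped_ellipsoid, init=RigidTransform.identity()
        )
        assert res.n_iterations <= 2
        assert res.transform.angle_deg < 1e-9
        assert res.psm < 1e-12

    def test_symmetric_result_independent_of_order(self, asymmetric_pair):
        a, b = asymmetric_pair
        diag = a.bounding_box_diagonal
        r_ab = icp_superimpose(a, b)
        r_ba = icp_superimpose(b, a)
        # both runs, expressed as A's pose relative to a fixed B
        pose1 = r_ab.transform.apply(a.points)
        pose2 = r_ba.transform.inverse().apply(a.points)
        assert np.abs(pose1 - pose2).max() < 1e-4 * diag

    def test_one_directional_is_order_dependent(self):
        """Partial overlap (a hole) exposes the classic ICP asymmetry."""
        from gpsa.synth import HoleSpec

        spec = PopulationSpec(
            noise_sigma=0.0,
            max_rotation_deg=15.0,
            max_translation=0.4,
            n_specimens=2,
            bumps=[BumpSpec(center=(1, -1, 1), amp_low=0.0, amp_high=0.5)],
            hole=HoleSpec(center=(0, 0, 1), angular_radius=0.6, specimens=(1,)),
            seed=9,
        )
        a, b = make_population(spec)[0]
        diag = a.bounding_box_diagonal
        params = ICPParams(symmetric=False)
        r_ab = icp_superimpose(a, b, params)
        r_ba = icp_superimpose(b, a, params)
        pose1 = r_ab.transform.apply(a.points)
        pose2 = r_ba.transform.inverse().apply(a.points)
        assert np.abs(pose1 - pose2).max() > 1e-4 * diag

    @pytest.mark.parametrize("seed", range(5))
    def test_cost_trace_non_increasing(self, seed):
        spec = PopulationSpec(n_specimens=2, seed=40 + seed)
        a, b = make_population(spec)[0]
        res = icp_superimpose(a, b)
        trace = np.array(res.cost_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1e-300))

    @pytest.mark.parametrize("seed", range(5))
    def test_psm_improves_on_a_coarse_start(self, asymmetric_pair, seed):
        """From a deliberately perturbed pose, superimposition ends at or
        below the starting surface-metric value.

        (From an already near-optimal pose the plane-cost optimum may sit
        at slightly higher point-to-point distance — the cost minimized is
        point-to-plane, not the metric itself.)
        """
        from gpsa.metric import psm

        a, b = asymmetric_pair
        perturb = random_rigid(300 + seed, max_angle_deg=10.0, max_trans=0.3)
        start = perturb.compose(select_init(a, b, init_candidates(a, b)))
        psm_start = psm(start.apply_to(a), b)
        res = icp_superimpose(a, b, init=start)
        assert res.psm <= psm_start + 1e-12
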