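import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taskcbct.geometry import (
    CArmGeometry,
    ProjectionMatrix,
    RigidTransform,
    ViewPose,
    angular_stats,
    apply_registration,
    grid_views,
    load_matrices,
    pose_to_matrix,
    save_matrices,
    tilted_orbit_views,
)


class TestGridViews:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(phi_start_deg=0, phi_end_deg=360, theta_min_deg=45,
                  theta_max_deg=135, step_deg=5), 72 * 19),
            (dict(phi_start_deg=0, phi_end_deg=360, theta_min_deg=90,
                  theta_max_deg=90, step_deg=360), 1),
            (dict(phi_start_deg=0, phi_end_deg=10, theta_min_deg=-25 + 90,
                  theta_max_deg=25 + 90, step_deg=5, phi_half_open=False), 3 * 11),
        ],
    )
    def test_exact_counts(self, kwargs, expected):
        assert len(grid_views(**kwargs)) == expected

    def test_eleven_theta_offsets(self):
        poses = grid_views(0, 5, 65, 115, 5)
        thetas = sorted({p.theta_deg for p in poses})
        assert len(thetas) == 11

    def test_lexicographic_order_and_canonicalization(self):
        poses = grid_views(350, 360, 85, 95, 5)
        assert [(p.phi_deg, p.theta_deg) for p in poses[:3]] == [
            (350, 85), (350, 90), (350, 95)
        ]

    def test_errors(self):
        with pytest.raises(ValueError):
            grid_views(0, 0, 45, 135, 5)
        with pytest.raises(ValueError):
            grid_views(0, 360, 45, 135, 7)  # step does not divide range
        with pytest.raises(ValueError):
            grid_views(0, 360, 45, 135, -5)

    @given(step=st.sampled_from([1, 2, 4, 5, 8, 10]), n_theta=st.integers(1, 5))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_half_open_count_formula(self, step, n_theta):
        poses = grid_views(0, 360, 90, 90 + (n_theta - 1) * step, step)
        assert len(poses) == (360 // step) * n_theta


class TestPoseToMatrix:
    def test_isocenter_hits_principal_point(self, geom):
        for pose in [ViewPose(0, 90), ViewPose(123, 71), ViewPose(300, 135)]:
            pix = pose_to_matrix(geom, pose).project(np.zeros(3))
            assert np.allclose(pix, geom.principal_point, atol=1e-9)

    def test_axis_point_row_independent_of_phi(self, geom):
        point = np.array([0.0, 0.0, 25.0])
        rows = [
            pose_to_matrix(geom, ViewPose(phi, 90)).project(point)[1]
            for phi in range(0, 360, 30)
        ]
        assert np.ptp(rows) < 1e-9

    def test_agrees_with_raycast_oracle(self, geom):
        """Pixel coords match an explicit ray/detector-plane intersection."""
        rng = np.random.default_rng(7)
        for pose in [ViewPose(33, 90), ViewPose(211, 60)]:
            matrix = pose_to_matrix(geom, pose)
            src = geom.source_position(pose)
            w = -src / np.linalg.norm(src)
            u = np.cross([0, 0, 1.0], w)
            u /= np.linalg.norm(u)
            v = np.cross(w, u)
            det_center = src + geom.source_to_detector_mm * w
            for _ in range(50):
                x = rng.uniform(-40, 40, 3)
                d = x - src
                hit = src + (geom.source_to_detector_mm / (d @ w)) * d
                expected = (
                    np.array([(hit - det_center) @ u, (hit - det_center) @ v])
                    / geom.pixel_pitch_mm
                    + geom.principal_point
                )
                assert np.abs(matrix.project(x) - expected).max() < 1e-6


class TestApplyRegistration:
    def test_identity(self, geom):
        p = pose_to_matrix(geom, ViewPose(10, 80))
        out = apply_registration(p, RigidTransform())
        assert np.allclose(out.entries, p.entries)

    def test_pure_translation_oracle(self, geom):
        p = pose_to_matrix(geom, ViewPose(45, 100))
        d = np.array([3.0, -7.0, 2.0])
        out = apply_registration(p, RigidTransform(np.eye(3), d))
        x = np.array([5.0, 8.0, -4.0])
        assert np.allclose(out.project(x), p.project(x - d), atol=1e-9)

    def test_inverse_composition_roundtrip(self, geom):
        p = pose_to_matrix(geom, ViewPose(0, 90))
        t = RigidTransform.from_euler_deg(4, -3, 10, (1.0, 2.0, -3.0))
        back = apply_registration(apply_registration(p, t), t.inverse())
        assert np.abs(back.entries - p.entries).max() < 1e-9

    def test_contravariant_composition(self, geom):
        """Adjusting by a composite transform equals adjusting step by step
        (with compose(a, b) applying b first, the step order reverses)."""
        p = pose_to_matrix(geom, ViewPose(70, 85))
        t1 = RigidTransform.from_euler_deg(2, 1, -4, (2.0, 0.0, 1.0))
        t2 = RigidTransform.from_euler_deg(-3, 5, 2, (-1.0, 3.0, 0.5))
        lhs = apply_registration(p, t2.compose(t1))  # t1 applied first
        rhs = apply_registration(apply_registration(p, t1), t2)
        assert np.allclose(lhs.entries, rhs.entries, atol=1e-9)

    def test_rejects_non_rigid(self, geom):
        p = pose_to_matrix(geom, ViewPose(0, 90))
        with pytest.raises(TypeError):
            apply_registration(p, np.eye(4))
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))


class TestTiltedOrbit:
    def test_untilted_reference_stays_in_plane(self):
        poses = tilted_orbit_views(0.0, 0.0, 36)
        assert np.allclose([p.theta_deg for p in poses], 90.0)

    @pytest.mark.parametrize("tilt", [5.0, 10.0, 25.0])
    def test_max_theta_excursion_equals_tilt(self, tilt):
        poses = tilted_orbit_views(tilt, 0.0, 720)
        dev = np.abs(np.array([p.theta_deg for p in poses]) - 90.0)
        assert abs(dev.max() - tilt) < 1e-6

    def test_matches_per_position_conversion_oracle(self):
        tilt, swivel = 10.0, 5.0
        angles = np.arange(0.0, 360.0, 7.5)
        poses = tilted_orbit_views(tilt, swivel, angles)
        t, s = np.deg2rad(tilt), np.deg2rad(swivel)
        rx = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
        ry = np.array([[np.cos(s), 0, np.sin(s)], [0, 1, 0], [-np.sin(s), 0, np.cos(s)]])
        for pose, a in zip(poses, angles):
            ar = np.deg2rad(a)
            d = ry @ rx @ np.array([np.cos(ar), np.sin(ar), 0.0])
            assert abs(pose.theta_deg - np.rad2deg(np.arccos(d[2]))) < 1e-9
            assert abs(pose.phi_deg - np.rad2deg(np.arctan2(d[1], d[0])) % 360) < 1e-9

    def test_rejects_excessive_tilt(self):
        with pytest.raises(ValueError):
            tilted_orbit_views(45.0, 0.0, 10)


class TestAngularStats:
    def _traj(self, pairs):
        return [ViewPose(phi, th) for phi, th in pairs]

    def test_identical_trajectories(self):
        t = self._traj([(0, 90), (5, 92), (10, 95)])
        assert angular_stats(t, t) == (0.0, 0.0)

    def test_constant_offset(self):
        a = self._traj([(0, 90), (5, 90), (10, 90)])
        b = self._traj([(0, 95), (5, 95), (10, 95)])
        assert angular_stats(a, b) == (5.0, 0.0)

    def test_hand_computed_three_views(self):
        a = self._traj([(0, 90), (5, 90), (10, 85)])
        b = self._traj([(0, 95), (5, 90), (10, 95)])
        mean, std = angular_stats(a, b)
        assert mean == pytest.approx(5.0)
        assert std == pytest.approx(4.082, abs=1e-3)  # population formula

    def test_phi_mismatch_raises(self):
        a = self._traj([(0, 90), (5, 90)])
        b = self._traj([(0, 90), (10, 90)])
        with pytest.raises(ValueError):
            angular_stats(a, b)


def test_matrix_npz_roundtrip(tmp_path, geom):
    poses = [ViewPose(phi, 90, t=i) for i, phi in enumerate([0, 30, 60])]
    mats = [pose_to_matrix(geom, p) for p in poses]
    path = tmp_path / "mats.npz"
    save_matrices(path, poses, mats)
    poses2, mats2 = load_matrices(path)
    assert [p.phi_deg for p in poses2] == [p.phi_deg for p in poses]
    assert all(np.allclose(a.entries, b.entries) for a, b in zip(mats, mats2))


def test_view_pose_invariants():
    assert ViewPose(370, 90).phi_deg == 10
    assert ViewPose(-5, 90).phi_deg == 355
    with pytest.raises(ValueError):
        ViewPose(0, 190)
    with pytest.raises(ValueError):
        CArmGeometry(source_to_isocenter_mm=900, source_to_detector_mm=800)
    with pytest.raises(ValueError):
        ProjectionMatrix(np.zeros((3, 4)))
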