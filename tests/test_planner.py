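import numpy as np
import pytest

from taskcbct.detectability import DetectabilityMap
from taskcbct.geometry import ViewPose
from taskcbct.planner import (
    OracleMapPredictor,
    PlannerState,
    Trajectory,
    circular_trajectory,
    next_view,
    plan_trajectory,
    retrospective_select,
)


def random_map(seed, phi_step=5.0):
    phis = np.arange(0.0, 360.0, phi_step)
    thetas = np.arange(45.0, 140.0, 5.0)
    rng = np.random.default_rng(seed)
    return DetectabilityMap(rng.random((len(phis), len(thetas))), phis, thetas)


class TestNextView:
    def test_lambda_zero_is_pure_argmax(self):
        state = PlannerState(current=ViewPose(0, 90, t=0), lam=0.0,
                             prev_direction=(5, 5))
        p = np.zeros(11)
        p[7] = 1.0  # delta = +10
        pose, idx = next_view(p, state)
        assert idx == 7 and pose.theta_deg == 100 and pose.phi_deg == 5

    def test_equal_predictions_continue_straight(self):
        state = PlannerState(current=ViewPose(10, 95, t=2), prev_direction=(5, 5))
        pose, idx = next_view(np.ones(11), state)
        assert pose.theta_deg == 100  # cosine maximized at zero turn

    def test_matches_exhaustive_scoring_oracle(self):
        """Winner equals a brute-force enumeration of all 11 scores."""
        state = PlannerState(current=ViewPose(10, 95, t=2),
                             prev_direction=(5, 5), lam=0.6)
        rng = np.random.default_rng(12)
        offsets = state.theta_offsets
        u = np.asarray(state.prev_direction)
        for _ in range(20):
            preds = rng.random(11)
            p_hat = (preds - preds.min()) / (preds.max() - preds.min())
            scores = []
            for i, d in enumerate(offsets):
                v = np.array([5.0, d])
                v = v / np.linalg.norm(v)
                scores.append(0.6 * (u @ v) + p_hat[i])
            _, idx = next_view(preds, state)
            assert idx == int(np.argmax(scores))

    def test_excludes_out_of_bounds_candidates(self):
        state = PlannerState(current=ViewPose(0, 50, t=0))
        p = np.zeros(11)
        p[0] = 1.0  # best at delta=-25 -> theta=25, out of [45,135]
        pose, idx = next_view(p, state)
        assert pose.theta_deg >= 45

    def test_all_candidates_out_of_bounds_raises(self):
        state = PlannerState(current=ViewPose(0, 90, t=0),
                             theta_abs_bounds=(89.0, 91.0),
                             theta_rel_bound_deg=1.0)
        # offsets are multiples of 5: every candidate except 0 violates the
        # +/-1 excursion; shrink bounds so even delta=0 is out
        state = PlannerState(current=ViewPose(0, 90, t=0),
                             theta_abs_bounds=(120.0, 135.0))
        with pytest.raises(ValueError):
            next_view(np.ones(11), state)

    def test_delta_menu_scales_with_phi_step(self):
        state = PlannerState(current=ViewPose(0, 90, t=0), delta_phi_deg=1.0)
        assert np.allclose(state.theta_offsets, np.arange(-5, 6))


class TestPlanTrajectory:
    def test_constant_theta_map_stays_flat(self):
        phis = np.arange(0.0, 360.0, 5.0)
        thetas = np.arange(45.0, 140.0, 5.0)
        rng = np.random.default_rng(0)
        d2 = np.tile(rng.random(len(phis))[:, None], (1, len(thetas)))
        m = DetectabilityMap(d2, phis, thetas)
        traj = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 40)
        assert np.all(traj.theta_deg == 90)

    def test_deterministic(self):
        m = random_map(5)
        a = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 40)
        b = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 40)
        assert np.array_equal(a.theta_deg, b.theta_deg)
        assert a.scores == b.scores

    @pytest.mark.parametrize("seed", range(50))
    def test_theta_constraints_never_violated(self, seed):
        m = random_map(seed)
        traj = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 72)
        assert traj.theta_deg.min() >= 45 and traj.theta_deg.max() <= 135
        assert np.abs(traj.theta_deg - 90).max() <= 45

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_property(self, seed):
        """Trajectories that reach the same (pose, direction) state under a
        deterministic predictor continue identically."""
        m = random_map(seed + 100)
        a = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 71)
        b = plan_trajectory(OracleMapPredictor(m), ViewPose(355, 90), 72)
        # b's second pose onward shares a's phi values: find state matches
        a_states = {}
        for t in range(1, len(a)):
            da = (a.phi_deg[t] - a.phi_deg[t - 1]) % 360, a.theta_deg[t] - a.theta_deg[t - 1]
            a_states[(a.phi_deg[t], a.theta_deg[t], da)] = t
        merged = False
        for t in range(1, len(b)):
            db = (b.phi_deg[t] - b.phi_deg[t - 1]) % 360, b.theta_deg[t] - b.theta_deg[t - 1]
            key = (b.phi_deg[t], b.theta_deg[t], db)
            if key in a_states:
                ta = a_states[key]
                n = min(len(a) - ta, len(b) - t)
                assert np.array_equal(a.theta_deg[ta:ta + n], b.theta_deg[t:t + n])
                merged = True
                break
        # merging is map-dependent; the assertion only fires when states meet
        if not merged:
            pytest.skip("trajectories never met in state for this map")

    def test_smoothness_limit_straight_line(self):
        """lambda -> inf: constant out-of-plane slope until a theta bound
        clips the line (pure smoothness limit)."""
        m = random_map(3)
        traj = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 40, lam=1e9)
        dtheta = np.diff(traj.theta_deg)
        slope = dtheta[0]
        for t in range(1, len(dtheta)):
            proposed = traj.theta_deg[t] + slope
            if not (45 <= proposed <= 135 and abs(proposed - 90) <= 45):
                break  # the straight continuation left the feasible band
            assert dtheta[t] == slope

    def test_phi_advances_by_fixed_increment(self):
        m = random_map(8)
        traj = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 40)
        dphi = np.diff(traj.phi_deg) % 360
        assert np.allclose(dphi, 5.0)


class TestRetrospectiveSelect:
    def test_exact_match_selected_and_removed(self):
        pool = [ViewPose(0, 90), ViewPose(5, 92), ViewPose(10, 88)]
        sel, rest = retrospective_select(ViewPose(5, 92), pool)
        assert (sel.phi_deg, sel.theta_deg) == (5, 92)
        assert len(rest) == 2

    def test_repeated_selection_returns_distinct_views(self):
        pool = [ViewPose(5, 90), ViewPose(5, 91), ViewPose(5, 89)]
        target = ViewPose(5, 90)
        seen = []
        for _ in range(3):
            sel, pool = retrospective_select(target, pool)
            seen.append((sel.phi_deg, sel.theta_deg))
        assert len(set(seen)) == 3
        with pytest.raises(ValueError):
            retrospective_select(target, pool)

    def test_tie_break_order(self):
        """Equidistant candidates: smaller |theta-90| wins, then smaller phi."""
        pool = [ViewPose(10, 95), ViewPose(0, 90), ViewPose(10, 85)]
        sel, _ = retrospective_select(ViewPose(5, 90), pool)
        assert (sel.phi_deg, sel.theta_deg) == (0, 90)
        pool = [ViewPose(0, 95), ViewPose(10, 95)]
        sel, _ = retrospective_select(ViewPose(5, 95), pool)
        assert sel.phi_deg == 0

    def test_phi_wraparound_distance(self):
        pool = [ViewPose(358, 90), ViewPose(20, 90)]
        sel, _ = retrospective_select(ViewPose(1, 90), pool)
        assert sel.phi_deg == 358


class TestTrajectoryIO:
    def test_csv_roundtrip_and_format(self, tmp_path):
        m = random_map(2)
        traj = plan_trajectory(OracleMapPredictor(m), ViewPose(0, 90), 10)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        text = path.read_text().splitlines()
        assert text[0] == "t,phi_deg,theta_deg"
        assert text[1].split(",")[1] == "0.000000"
        back = Trajectory.from_csv(path)
        assert np.array_equal(back.theta_deg, traj.theta_deg)

    def test_circular_trajectory(self):
        c = circular_trajectory(ViewPose(10, 90), 40, 5.0)
        assert len(c) == 40
        assert np.all(c.theta_deg == 90)
        assert c.phi_deg[-1] == (10 + 39 * 5) % 360
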