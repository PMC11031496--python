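import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navscape.metrics import (auc_speed_accuracy, drop_error,
                              enumerate_path_ids, idle_time, lisas,
                              path_metrics, periphery_preference,
                              speed_accuracy, trial_paths)
from navscape.records import DropEvent, Trajectory


def make_traj(xy, dt=0.1):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * dt
    return Trajectory(t, xy[:, 0], xy[:, 1], np.array(["dropoff_nav"] * len(xy)))


def make_events(rts, des):
    """Events with prescribed navigation durations and drop errors."""
    t, out = 0.0, []
    for i, (rt, de) in enumerate(zip(rts, des)):
        out.append(DropEvent(0, i + 1, t, t + rt, (de, 0.0), (0.0, 0.0)))
        t += rt
    return out


in_disc = st.tuples(st.floats(-3500, 3500), st.floats(-3500, 3500))


class TestDropError:
    def test_identity_and_pythagoras(self):
        assert drop_error((1.0, 2.0), (1.0, 2.0)) == 0.0
        assert drop_error((3000.0, 4000.0), (0.0, 0.0)) == 5000.0

    def test_antipodal_boundary_points_reach_arena_diameter(self):
        assert drop_error((5000.0, 0.0), (-5000.0, 0.0)) == 10000.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            drop_error((float("nan"), 0.0), (0.0, 0.0))

    @settings(deadline=None, max_examples=100)
    @given(a=in_disc, b=in_disc, c=in_disc)
    def test_triangle_inequality_and_disc_bound(self, a, b, c):
        assert drop_error(a, c) <= drop_error(a, b) + drop_error(b, c) + 1e-7
        assert drop_error(a, b) <= 2 * 5000.0


class TestPeripheryPreference:
    def test_pure_peripheral_and_pure_central(self):
        outer = make_traj([(4000.0, 0.0)] * 4)
        inner = make_traj([(0.0, 0.0)] * 4)
        assert periphery_preference(outer, 5000.0) == 1.0
        assert periphery_preference(inner, 5000.0) == 0.0

    def test_sample_proportion(self):
        traj = make_traj([(1000, 0), (0, 1000), (-1000, 0), (4000, 0)])
        assert periphery_preference(traj, 5000.0) == 0.25

    def test_equal_area_boundary_is_wider(self):
        # samples at 3000 U.u.: beyond R/2 but inside R/sqrt(2)
        traj = make_traj([(3000.0, 0.0)] * 3)
        assert periphery_preference(traj, 5000.0) == 1.0
        assert periphery_preference(traj, 5000.0, boundary="equal_area") == 0.0

    def test_empty_after_phase_filter_raises(self):
        traj = make_traj([(0, 0), (10, 0)])
        with pytest.raises(ValueError):
            periphery_preference(traj, 5000.0, phase="retrieval")


class TestPathMetrics:
    def test_straight_path_is_unit_sinuosity(self):
        xy = [(i * 100.0, 0.0) for i in range(11)]
        pm = path_metrics(make_traj(xy), ((0.0, 0.0), (1000.0, 0.0)),
                         idle_speed_eps=1.0)
        assert pm.sinuosity == pytest.approx(1.0)
        assert pm.x_flips == 0 and pm.y_flips == 0
        assert pm.max_abs_deviation == pytest.approx(0.0)

    def test_right_angle_legs_345(self):
        # 3000 east then 4000 north; crow = 5000
        xy = [(0, 0), (1500, 0), (3000, 0), (3000, 2000), (3000, 4000)]
        pm = path_metrics(make_traj(xy), ((0.0, 0.0), (3000.0, 4000.0)),
                         idle_speed_eps=1.0)
        assert pm.distance_traveled == pytest.approx(7000.0)
        assert pm.crow_distance == pytest.approx(5000.0)
        assert pm.sinuosity == pytest.approx(1.4)

    def test_x_flip_count_debounced(self):
        # x-velocity sign pattern +, +, -, + with large displacements
        xy = [(0, 0), (100, 0), (200, 0), (120, 0), (220, 0)]
        pm = path_metrics(make_traj(xy), ((0, 0), (220, 0)),
                         idle_speed_eps=1.0, flip_min_disp=50.0)
        assert pm.x_flips == 2

    def test_jitter_below_min_disp_is_ignored(self):
        # 10-unit backtrack amid forward motion: below the 50-unit debounce
        xy = [(0, 0), (100, 0), (90, 0), (200, 0)]
        pm = path_metrics(make_traj(xy), ((0, 0), (200, 0)),
                         idle_speed_eps=1.0, flip_min_disp=50.0)
        assert pm.x_flips == 0

    def test_zero_crow_distance_flags_sinuosity_undefined(self):
        xy = [(0, 0), (500, 0), (0, 0)]
        pm = path_metrics(make_traj(xy), ((0.0, 0.0), (0.0, 0.0)),
                         idle_speed_eps=1.0)
        assert math.isnan(pm.sinuosity)
        assert not pm.sinuosity_defined
        assert pm.distance_traveled == pytest.approx(1000.0)

    def test_max_abs_deviation_of_triangle_detour(self):
        xy = [(0, 0), (500, 300), (1000, 0)]
        pm = path_metrics(make_traj(xy), ((0.0, 0.0), (1000.0, 0.0)),
                         idle_speed_eps=1.0)
        assert pm.max_abs_deviation == pytest.approx(300.0)

    def test_distance_matches_brute_force_on_random_paths(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            xy = rng.uniform(-4000, 4000, size=(20, 2))
            pm = path_metrics(make_traj(xy), (xy[0], xy[-1]), idle_speed_eps=1.0)
            brute = sum(math.dist(xy[i], xy[i + 1]) for i in range(len(xy) - 1))
            assert pm.distance_traveled == pytest.approx(brute, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            path_metrics(make_traj([(0, 0)]), ((0, 0), (1, 1)), idle_speed_eps=1.0)


class TestIdleTime:
    def test_constant_fast_motion_has_no_idle(self):
        xy = [(i * 100.0, 0.0) for i in range(11)]
        assert idle_time(make_traj(xy), idle_speed_eps=5.0) == 0.0

    def test_stationary_gap_is_summed(self):
        # 1 s of motion, 2 s stationary, 7 s motion (dt = 1 s)
        xy = [(0, 0), (100, 0), (100, 0), (100, 0)] + \
             [(100 + i * 100, 0) for i in range(1, 8)]
        traj = make_traj(xy, dt=1.0)
        assert idle_time(traj, idle_speed_eps=5.0) == pytest.approx(2.0)

    def test_fully_stationary_equals_total_duration(self):
        traj = make_traj([(50.0, 50.0)] * 11, dt=1.0)
        assert idle_time(traj, idle_speed_eps=5.0) == pytest.approx(10.0)


class TestLisas:
    def test_zero_drop_errors_recover_rt(self):
        ev = make_events([5.0, 7.0, 9.0], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(lisas(ev), [5.0, 7.0, 9.0])

    def test_hand_computed_example(self):
        # SD_RT = 2 (rts 8,10,12), SD_DE = 1000 (des 1500,500,2500)
        ev = make_events([8.0, 10.0, 12.0], [1500.0, 500.0, 2500.0])
        vals = lisas(ev)
        assert np.std([8, 10, 12], ddof=1) == pytest.approx(2.0)
        assert np.std([1500, 500, 2500], ddof=1) == pytest.approx(1000.0)
        assert vals[1] == pytest.approx(10.0 + (2.0 / 1000.0) * 500.0)  # 11.0 s

    def test_scale_invariance_in_drop_error_units(self):
        ev1 = make_events([8.0, 10.0, 12.0], [1500.0, 500.0, 2500.0])
        ev2 = make_events([8.0, 10.0, 12.0], [3000.0, 1000.0, 5000.0])
        np.testing.assert_allclose(lisas(ev1), lisas(ev2))

    def test_affine_in_drop_error(self):
        ev = make_events([8.0, 10.0, 12.0], [1500.0, 500.0, 2500.0])
        rt = np.array([8.0, 10.0, 12.0])
        de = np.array([1500.0, 500.0, 2500.0])
        slope = np.std(rt, ddof=1) / np.std(de, ddof=1)
        np.testing.assert_allclose(lisas(ev), rt + slope * de)

    def test_constant_nonzero_errors_raise(self):
        ev = make_events([5.0, 7.0], [800.0, 800.0])
        with pytest.raises(ValueError):
            lisas(ev)

    def test_single_trial_raises(self):
        with pytest.raises(ValueError):
            lisas(make_events([5.0], [100.0]))


class TestAuc:
    def test_constant_error_gives_rectangle(self):
        ev = make_events([2.0, 3.0, 5.0], [400.0, 400.0, 400.0])
        assert auc_speed_accuracy(ev) == pytest.approx(400.0 * 10.0)

    def test_linear_decay_gives_triangle(self):
        # DE falling linearly 1000 -> 0 over cumulative RT 0 -> 10
        n = 200
        rts = [10.0 / n] * n
        des = [1000.0 * (1 - (i + 1) / n) for i in range(n)]
        assert auc_speed_accuracy(make_events(rts, des)) == pytest.approx(5000.0, rel=0.01)

    def test_zero_errors_give_zero_area(self):
        ev = make_events([2.0, 3.0], [0.0, 0.0])
        assert auc_speed_accuracy(ev) == 0.0

    def test_single_event_undefined(self):
        with pytest.raises(ValueError):
            auc_speed_accuracy(make_events([2.0], [100.0]))


class TestPathEnumeration:
    def test_36_unordered_pairs_of_nine_locations(self):
        ids = enumerate_path_ids(8)
        assert len(ids) == 36
        assert len(set(ids)) == 36
        points = {p for pair in ids for p in pair}
        assert points == {"start", 0, 1, 2, 3, 4, 5, 6, 7}

    def test_trial_paths_on_simulated_session(self, beeline_session):
        traj, events = beeline_session
        table = trial_paths(traj, events, idle_speed_eps=6.5)
        assert len(table) >= len(events) - 1
        valid = {str(p) for p in enumerate_path_ids(8)}
        same_loc = {str((i, i)) for i in range(8)}
        assert set(table["path_id"]) <= valid | same_loc
        # beeline navigator: near-straight paths between distinct locations
        distinct = table[table["crow_distance"] > 0]
        assert (distinct["sinuosity"] >= 1.0 - 1e-9).all()


def test_speed_accuracy_bundles_consistent_values():
    ev = make_events([8.0, 10.0, 12.0], [1500.0, 500.0, 2500.0])
    sa = speed_accuracy(ev)
    assert sa.auc == pytest.approx(auc_speed_accuracy(ev))
    np.testing.assert_allclose(sa.lisas, lisas(ev))
    assert sa.sd_rt == pytest.approx(2.0)
    assert sa.sd_de == pytest.approx(1000.0)
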