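import numpy as np
import pytest

from lanelab import (
    ClusteringParams,
    CorridorGeometry,
    FixtureSpec,
    TrajectorySet,
    classify_phase,
    cluster_count_series,
    clusters_at,
    is_following,
    make_disordered_fixture,
    make_lane_fixture,
    make_switching_fixture,
    sensitivity_scan,
    survival_curve,
    track_lifetimes,
)
from lanelab.clustering import ClusterTimeline, OutOfWindowError

from _oracles import product_limit, unionfind_clusters
from conftest import RING, assert_partition

DEFAULTS = ClusteringParams()


def arc_trajectory(arc_offsets, speeds, duration=5.0, r=3.25, rate=10.0,
                   directions=None):
    """Pedestrians on one circle, given initial arc positions and speeds."""
    times = np.arange(0.0, duration + 1e-9, 1.0 / rate)
    n = len(arc_offsets)
    theta = (np.asarray(arc_offsets)[None, :] +
             np.asarray(speeds)[None, :] * times[:, None]) / r
    positions = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)
    dirs = directions if directions is not None else np.ones(n, dtype=int)
    return TrajectorySet(times=times, positions=positions, directions=dirs,
                         geometry=RING)


class TestIsFollowing:
    def test_already_within_delta(self):
        traj = arc_trajectory([0.0, 0.3], [1.2, 1.2])
        assert is_following(traj, 1, 0, 0.0)

    def test_two_metres_behind_at_matched_speed(self):
        # closest approach to the reference point over 1 s is ~1 m >= delta
        traj = arc_trajectory([2.0, 0.0], [1.0, 1.0])
        assert not is_following(traj, 1, 0, 0.0)

    def test_approaching_from_behind(self):
        # 0.9 m behind the fixed reference point, walking 1.2 m/s: passes it
        traj = arc_trajectory([0.9, 0.0], [1.2, 1.2])
        assert is_following(traj, 1, 0, 0.0)

    def test_self_follow_undefined(self):
        traj = arc_trajectory([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            is_following(traj, 0, 0, 0.0)

    def test_out_of_window_query(self):
        traj = arc_trajectory([0.0, 1.0], [1.0, 1.0], duration=2.0)
        with pytest.raises(OutOfWindowError):
            is_following(traj, 1, 0, 1.5)


class TestClustersAt:
    def test_single_file_chains_transitively(self):
        traj = arc_trajectory([0.0, 0.4, 0.8], [1.2] * 3)
        parts = clusters_at(traj, 0.0)
        assert parts == [frozenset({0, 1, 2})]

    def test_dispersed_crowd_is_all_singletons(self):
        # pairwise separations far above delta + v*window
        traj = arc_trajectory([0.0, 5.0, 10.0], [1.0] * 3)
        parts = clusters_at(traj, 0.0)
        assert len(parts) == 3
        assert_partition(parts, [0, 1, 2])

    def test_opposite_directions_never_merge(self):
        # head-on pass well within delta, but circulation signs differ
        traj = arc_trajectory([0.0, 0.3, 2.0, 2.3], [1.0, 1.0, -1.0, -1.0],
                              directions=np.array([1, 1, -1, -1]))
        parts = clusters_at(traj, 0.8)
        assert len(parts) == 2
        assert frozenset({0, 1}) in parts and frozenset({2, 3}) in parts

    def test_direction_agnostic_switch(self):
        traj = arc_trajectory([0.0, 0.3], [1.0, -1.0],
                              directions=np.array([1, -1]))
        params = ClusteringParams(same_direction_only=False)
        assert clusters_at(traj, 0.0, params) == [frozenset({0, 1})]

    def test_matches_unionfind_oracle_on_random_scenes(self):
        for seed in range(6):
            traj = make_disordered_fixture(n=8 + seed % 3, duration=4.0,
                                           seed=seed, step_std=0.25)
            for t in (0.0, 1.0, 2.0):
                got = set(clusters_at(traj, t))
                want = unionfind_clusters(traj, t, DEFAULTS.delta, DEFAULTS.window)
                assert got == want


class TestCountSeries:
    def test_two_lane_fixture_counts_two(self):
        traj = make_lane_fixture(FixtureSpec(duration=10.0))
        _, counts = cluster_count_series(traj)
        assert np.all(counts == 2)

    def test_static_dispersed_counts_n(self):
        times = np.arange(0.0, 5.01, 0.1)
        theta = np.linspace(0, 2 * np.pi, 7)[:-1]
        pos = np.tile(3.25 * np.stack([np.cos(theta), np.sin(theta)], -1),
                      (times.size, 1, 1))
        traj = TrajectorySet(times=times, positions=pos,
                             directions=np.ones(6, dtype=int), geometry=RING)
        _, counts = cluster_count_series(traj)
        assert np.all(counts == 6)

    def test_partition_property_every_frame(self, short_run_n20):
        frames, _ = cluster_count_series(short_run_n20)
        for t in frames[::20]:
            assert_partition(clusters_at(short_run_n20, t),
                             short_run_n20.ids.tolist())

    def test_monotone_in_delta_and_window(self, short_run_n20):
        base = cluster_count_series(short_run_n20, ClusteringParams(0.6, 1.0))[1]
        wider = cluster_count_series(short_run_n20, ClusteringParams(0.9, 1.0))[1]
        longer = cluster_count_series(short_run_n20, ClusteringParams(0.6, 1.5))[1]
        assert np.all(wider <= base)
        # a longer window admits fewer evaluation frames; compare the shared ones
        assert np.all(longer <= base[:longer.size])


class TestClassifyPhase:
    @pytest.mark.parametrize("count, phase", [
        (1, "order"), (4, "order"), (5, "order"),
        (7, "intermediate"), (9, "intermediate"),
        (10, "disorder"), (12, "disorder"),
    ])
    def test_bands(self, count, phase):
        assert classify_phase(count) == phase

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            classify_phase(0)


class TestLifetimes:
    def test_switching_fixture_lifetimes_equal_period(self):
        part_a = [(0, 1), (2, 3)]
        part_b = [(0, 2), (1, 3)]
        traj = make_switching_fixture(part_a, part_b, period=2.0, duration=20.0)
        tl = track_lifetimes(traj)
        assert tl.lifetimes.size > 0
        np.testing.assert_allclose(tl.lifetimes, 2.0)

    def test_static_fixture_all_censored(self):
        traj = make_lane_fixture(FixtureSpec(duration=30.0))
        tl = track_lifetimes(traj)
        assert tl.lifetimes.size == 0
        assert tl.censored.size == 2
        np.testing.assert_allclose(tl.censored, 30.0 - DEFAULTS.window, atol=0.11)

    def test_membership_growth_kills_old_cluster(self):
        # {0,1} alone for one period, then merged with {2}: the pair's
        # completed lifetime equals the period
        traj = make_switching_fixture([(0, 1), (2,)], [(0, 1, 2)],
                                      period=1.0, duration=10.0)
        tl = track_lifetimes(traj)
        assert np.all(np.isin(tl.lifetimes, [1.0]))


class TestSurvival:
    def test_empirical_survival_without_censoring(self):
        tl = ClusterTimeline(None, None, np.array([1.0, 2.0, 3.0]), np.array([]))
        sc = survival_curve(tl)
        # step function: p(1.5) is the level after the death at t = 1
        p = sc.probabilities[np.searchsorted(sc.times, 1.5, side="right") - 1]
        assert p == pytest.approx(2 / 3)
        assert sc.probabilities[0] <= 1.0
        assert np.all(np.diff(sc.probabilities) <= 1e-12)

    def test_product_limit_with_censoring(self):
        tl = ClusterTimeline(None, None, np.array([2.0, 2.0]), np.array([3.0]))
        sc = survival_curve(tl)
        t_o, s_o = product_limit([2.0, 2.0, 3.0], [1, 1, 0])
        for t, s in zip(t_o, s_o):
            idx = np.searchsorted(sc.times, t)
            assert sc.probabilities[idx] == pytest.approx(s)

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError):
            survival_curve(ClusterTimeline(None, None, np.array([]), np.array([])))


class TestSensitivity:
    def test_singleton_grid_matches_count_series(self):
        traj = make_lane_fixture(FixtureSpec(duration=8.0))
        table = sensitivity_scan(traj, [0.6], [1.0])
        _, counts = cluster_count_series(traj)
        assert table.iloc[0, 0] == pytest.approx(counts.mean())

    def test_vanishing_delta_gives_all_singletons(self):
        traj = make_lane_fixture(FixtureSpec(duration=8.0))
        table = sensitivity_scan(traj, [1e-6], [1.0])
        assert table.iloc[0, 0] == pytest.approx(traj.n_pedestrians)

    def test_lane_fixture_flat_over_robust_band(self):
        traj = make_lane_fixture(FixtureSpec(duration=10.0))
        table = sensitivity_scan(traj, [0.4, 0.6, 0.8], [0.5, 1.0, 1.5])
        assert np.all(table.to_numpy() == 2.0)
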