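import numpy as np
import pytest

from lanelab import (
    CorridorGeometry,
    CrowdState,
    ModelParams,
    SimulationConfig,
    collision_distance,
    contact_forces,
    desired_direction,
    desired_speed,
    run_simulation,
    step,
    update_destination,
)
from lanelab.model import _free_paths

from _oracles import euler_relaxation_speed, stepping_collision_distance
from conftest import OPEN_FIELD, RING

PARAMS = ModelParams()


def single_agent(position, velocity=(0.0, 0.0), v0=1.2, direction=1):
    return CrowdState(positions=[position], velocities=[velocity],
                      v0=[v0], directions=[direction], radii=[0.2])


def crowd(positions, velocities=None, v0=1.2, directions=None):
    n = len(positions)
    velocities = velocities if velocities is not None else np.zeros((n, 2))
    directions = directions if directions is not None else np.ones(n, dtype=int)
    return CrowdState(positions=positions, velocities=velocities,
                      v0=np.full(n, v0), directions=directions,
                      radii=np.full(n, 0.2))


class TestCollisionDistance:
    def test_radial_ray_to_outer_wall(self):
        state = single_agent((3.25, 0.0))
        # contact when the body surface reaches the wall: 4.5 - 3.25 - 0.2
        assert collision_distance(state, 0, 0.0, PARAMS, RING) == pytest.approx(1.05)

    def test_tangential_ray_from_inner_edge(self):
        state = single_agent((2.2, 0.0))
        expected = np.sqrt(4.3**2 - 2.2**2)        # chord to the outer contact circle
        got = collision_distance(state, 0, np.pi / 2, PARAMS, RING)
        assert got == pytest.approx(expected, abs=1e-9)
        oracle = stepping_collision_distance(
            np.array([[2.2, 0.0]]), np.zeros((1, 2)), np.array([1.2]),
            np.array([0.2]), 0, np.pi / 2, 2.0, 4.5, 10.0)
        assert abs(got - oracle) <= 0.005

    def test_stationary_neighbour_dead_ahead(self):
        state = crowd([(0.0, 3.0), (1.0, 3.0)])
        assert collision_distance(state, 0, 0.0, PARAMS, RING) == pytest.approx(0.6)

    def test_free_ray_capped_at_horizon(self):
        state = single_agent((500.0, 0.0))
        assert collision_distance(state, 0, 0.0, PARAMS, OPEN_FIELD) == PARAMS.d_max

    def test_matches_stepping_oracle_on_random_scenes(self):
        rng = np.random.default_rng(12345)
        for _ in range(25):
            n = rng.integers(2, 6)
            r = np.sqrt(rng.uniform(2.3**2, 4.2**2, n))
            th = rng.uniform(0, 2 * np.pi, n)
            pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
            if np.min(np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
                      + np.eye(n) * 9) < 0.45:
                continue  # only physically reachable (non-touching) scenes
            vel = rng.normal(0, 0.8, (n, 2))
            v0 = rng.uniform(0.8, 1.5, n)
            state = CrowdState(positions=pos, velocities=vel, v0=v0,
                               directions=np.ones(n, dtype=int),
                               radii=np.full(n, 0.2))
            alpha = rng.uniform(0, 2 * np.pi)
            got = collision_distance(state, 0, alpha, PARAMS, RING)
            want = stepping_collision_distance(pos, vel, v0, np.full(n, 0.2),
                                               0, alpha, 2.0, 4.5, 10.0)
            assert abs(got - want) <= 0.005

    def test_numpy_reference_matches_fast_kernel(self):
        from lanelab import _fast

        rng = np.random.default_rng(99)
        n = 8
        r = np.sqrt(rng.uniform(2.3**2, 4.2**2, n))
        th = rng.uniform(0, 2 * np.pi, n)
        pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        vel = rng.normal(0, 0.5, (n, 2))
        v0 = rng.uniform(0.8, 1.5, n)
        radii = np.full(n, 0.2)
        alphas = rng.uniform(0, 2 * np.pi, (n, 61))
        ref = _free_paths(pos, vel, v0, radii, alphas, PARAMS, RING)
        fast = _fast.free_paths_kernel(pos, vel, v0, radii, alphas,
                                       PARAMS.d_max, RING.r_inner, RING.r_outer)
        np.testing.assert_allclose(ref, fast, atol=1e-12)


class TestDesiredDirection:
    def test_free_space_goes_straight(self):
        state = single_agent((500.0, 0.0))
        dec = desired_direction(state, 0, PARAMS, OPEN_FIELD)
        assert dec.alpha_des == pytest.approx(dec.alpha0)
        assert np.all(dec.f_samples == PARAMS.d_max)
        assert dec.v_des == pytest.approx(1.2)

    def test_obstacle_on_ray_forces_deviation(self):
        # blocker exactly on the looking direction (tangent at theta=0 is +y)
        state = crowd([(500.0, 0.0), (500.0, 1.0)])
        dec = desired_direction(state, 0, PARAMS, OPEN_FIELD, rng=np.random.default_rng(0))
        assert dec.alpha_des != pytest.approx(dec.alpha0)
        # exhaustive check: returned heading minimises d(alpha) over the grid
        offsets = PARAMS.heading_offsets()
        d = np.sqrt(PARAMS.d_max**2 + dec.f_samples**2
                    - 2 * PARAMS.d_max * dec.f_samples * np.cos(offsets))
        chosen = np.argmin(np.abs(offsets - (dec.alpha_des - dec.alpha0)))
        assert d[chosen] == pytest.approx(d.min())

    def test_offset_obstacle_pushes_to_other_side(self):
        # an obstacle slightly left of the looking direction occludes the
        # straight ray (a 0.4 m contact disc at 1 m subtends ~24 deg), so
        # the cheaper escape is a rightward deviation
        ang = np.pi / 2 + np.deg2rad(10.0)
        state = crowd([(500.0, 0.0), (500.0 + 1.0 * np.cos(ang), 1.0 * np.sin(ang))])
        dec = desired_direction(state, 0, PARAMS, OPEN_FIELD)
        assert dec.alpha_des < dec.alpha0

    def test_decision_within_vision_field(self):
        state = crowd([(3.0, 0.0), (3.0, 0.6), (2.6, 0.3)])
        dec = desired_direction(state, 0, PARAMS, RING)
        assert abs(dec.alpha_des - dec.alpha0) <= PARAMS.vision_half_angle_rad + 1e-12


class TestDesiredSpeed:
    @pytest.mark.parametrize("v0, d_h, tau, expected", [
        (1.2, 10.0, 0.5, 1.2),
        (1.2, 0.0, 0.5, 0.0),
        (1.2, 0.3, 0.5, 0.6),
    ])
    def test_min_rule(self, v0, d_h, tau, expected):
        assert desired_speed(v0, d_h, tau) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            desired_speed(1.2, -0.1, 0.5)


class TestContactForces:
    def test_no_overlap_no_force(self):
        state = crowd([(3.0, 0.0), (3.0, 0.5)])
        np.testing.assert_allclose(contact_forces(state, 0, PARAMS, RING), 0.0)

    def test_pair_overlap_magnitude(self):
        state = crowd([(3.0, 0.0), (3.39, 0.0)])
        f = contact_forces(state, 0, PARAMS, RING)
        # overlap 0.01 m, k = 1e3 -> magnitude 10, pushing away from neighbour
        assert np.linalg.norm(f) == pytest.approx(10.0)
        assert f[0] < 0 and f[1] == pytest.approx(0.0)

    def test_outer_wall_overlap_pushes_inward(self):
        state = crowd([(4.32, 0.0)])                  # 0.02 m beyond wall contact
        f = contact_forces(state, 0, PARAMS, RING)
        assert f[0] == pytest.approx(-20.0)
        assert f[1] == pytest.approx(0.0)

    def test_coincident_centres_degenerate(self):
        state = crowd([(3.0, 0.0), (3.0, 0.0)])
        with pytest.raises(ValueError):
            contact_forces(state, 0, PARAMS, RING)


class TestDestination:
    @pytest.mark.parametrize("pos, direction, expected", [
        ((3.0, 0.0), +1, (3.0, 5.0)),
        ((0.0, 3.0), +1, (-5.0, 3.0)),
        ((3.0, 0.0), -1, (3.0, -5.0)),
    ])
    def test_tangent_destination(self, pos, direction, expected):
        np.testing.assert_allclose(
            update_destination(np.array(pos), direction, 5.0), expected, atol=1e-12)


class TestStep:
    def test_free_flow_speed_relaxation_matches_discrete_closed_form(self):
        params = ModelParams()
        state = single_agent((500.0, 0.0))
        for _ in range(int(round(0.5 / params.dt))):
            state = step(state, params, OPEN_FIELD)
        speed = np.linalg.norm(state.velocities[0])
        want = euler_relaxation_speed(1.2, params.tau, params.dt, 0.5)
        assert speed == pytest.approx(want, abs=1e-6)
        # and the continuous closed form v0*(1 - e^-t/tau) up to O(dt)
        assert speed == pytest.approx(1.2 * (1 - np.exp(-1.0)), abs=0.03)

    def test_cruising_state_is_fixed_point(self):
        state = single_agent((500.0, 0.0), velocity=(0.0, 1.2))
        new = step(state, PARAMS, OPEN_FIELD)
        np.testing.assert_allclose(new.velocities, state.velocities, atol=1e-9)

    def test_overlapping_pair_pushed_apart(self):
        state = crowd([(3.0, 0.0), (3.35, 0.0)])
        new = step(state, PARAMS, RING)
        rel = new.velocities[1] - new.velocities[0]
        assert rel[0] > 0          # separating along the line of centres

    def test_instability_detected(self):
        state = single_agent((3.0, 0.0), velocity=(1e308, 0.0))
        with pytest.raises(FloatingPointError):
            step(state, PARAMS, RING)


class TestRunSimulation:
    def test_two_agents_reach_cruising_speed(self):
        traj = run_simulation(SimulationConfig(n=2, sigma=0.0, duration=10.0, seed=3))
        speeds = np.linalg.norm(traj.velocities()[-20:], axis=-1)
        assert np.all(np.abs(speeds - 1.2) < 0.05)

    def test_seeded_rerun_is_byte_identical(self):
        cfg = SimulationConfig(n=12, sigma=0.16, duration=5.0, seed=11)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.v0, b.v0)
        assert np.array_equal(a.directions, b.directions)

    def test_containment(self, runs_n60):
        r = runs_n60[0].radii()
        assert r.min() >= 2.0 - 0.05
        assert r.max() <= 4.5 + 0.05

    def test_speed_bound_without_contacts(self):
        traj = run_simulation(SimulationConfig(n=2, sigma=0.0, duration=10.0, seed=5))
        speeds = np.linalg.norm(traj.velocities(), axis=-1)
        assert speeds.max() < 1.2 + 0.1

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError):
            run_simulation(SimulationConfig(
                n=40, sigma=0.0, duration=1.0, seed=0,
                geometry=CorridorGeometry(2.0, 2.5)))

    def test_unidirectional_flag(self):
        traj = run_simulation(SimulationConfig(n=6, sigma=0.0, duration=2.0,
                                               seed=1, unidirectional=True))
        assert np.all(traj.directions == 1)

    def test_timestep_convergence_in_free_flow(self):
        # near-straight free flow: the 10 s trajectory error against a fine
        # reference shrinks linearly with dt (first-order integrator) and is
        # below 1 cm by dt = 0.0125
        def positions(dt):
            cfg = SimulationConfig(n=1, sigma=0.0, duration=10.0, seed=2,
                                   geometry=OPEN_FIELD, unidirectional=True,
                                   params=ModelParams(dt=dt))
            return run_simulation(cfg).positions

        ref = positions(0.005)
        err = {dt: np.linalg.norm(positions(dt) - ref, axis=-1).max()
               for dt in (0.05, 0.025, 0.0125)}
        assert err[0.05] > err[0.025] > err[0.0125]
        assert err[0.025] < 2.1 * err[0.0125] * 2   # ~first order in dt
        assert err[0.0125] < 0.01
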