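import numpy as np
import pytest

from conftest import brute_force_neighbors, random_state
from swarmevo.dynamics import (
    AgentState,
    SocialParams,
    Traits,
    autonomous_force,
    force_balance_distance,
    interaction_graph,
    neighbor_arrays,
    neighbor_sets,
    pair_force_coeff,
    pair_potential,
    response_speed_param,
    social_force,
    step,
)
from swarmevo.geometry import TorusGeometry


class TestParams:
    def test_repulsion_must_be_shorter_ranged(self):
        with pytest.raises(ValueError):
            SocialParams(repulsion_length=8.0, attraction_length=7.5)

    def test_contact_force_must_be_repulsive(self):
        with pytest.raises(ValueError):
            SocialParams(repulsion_strength=0.1, attraction_strength=1.0,
                         repulsion_length=1.0, attraction_length=7.5)

    def test_derived_ratios(self, params):
        assert params.strength_ratio == pytest.approx(1.1)
        assert params.length_ratio == pytest.approx(1.0 / 7.5)


class TestNeighborSets:
    def test_pair_within_range(self, params, geometry):
        state = AgentState(np.array([[10.0, 10.0], [13.0, 10.0]]), np.zeros((2, 2)))
        traits = Traits.uniform(2, 1.0, 0.0, 30.0)
        nbrs = neighbor_sets(state, traits, params, geometry)
        assert list(nbrs[0]) == [1] and list(nbrs[1]) == [0]

    def test_short_range_agent_is_asocial(self, params, geometry):
        state = AgentState(np.array([[10.0, 10.0], [15.0, 10.0], [20.0, 10.0]]),
                           np.zeros((3, 2)))
        traits = Traits(np.ones(3), np.zeros(3), np.array([2.0, 30.0, 30.0]))
        nbrs = neighbor_sets(state, traits, params, geometry)
        assert len(nbrs[0]) == 0  # everyone beyond its lmax=2
        assert 0 in nbrs[1]  # but it still influences others

    def test_crowd_saturates_at_k(self, rng, params, geometry):
        state = random_state(rng, 30, TorusGeometry(20.0))
        traits = Traits.uniform(30, 1.0, 0.0, 30.0)
        nbrs = neighbor_sets(state, traits, params, TorusGeometry(20.0))
        assert all(len(nb) == params.neighbor_count for nb in nbrs)

    @pytest.mark.parametrize("seed", range(5))
    def test_kernel_matches_brute_force(self, seed, params):
        geom = TorusGeometry(60.0)
        rng = np.random.default_rng(seed)
        state = random_state(rng, 40, geom)
        lmax = rng.uniform(0.0, 30.0, 40)
        traits = Traits(np.ones(40), np.zeros(40), lmax)
        ref = brute_force_neighbors(state.positions, lmax, params.neighbor_count, geom)
        nbr, counts = neighbor_arrays(state, traits, params, geom)
        for i in range(40):
            assert counts[i] == len(ref[i])
            np.testing.assert_array_equal(nbr[i, : counts[i]], ref[i])


class TestSocialForce:
    def test_no_neighbors_zero(self, params, geometry):
        state = AgentState(np.array([[1.0, 1.0]]), np.zeros((1, 2)))
        f = social_force(0, state, np.array([], dtype=int), params, geometry)
        np.testing.assert_array_equal(f, np.zeros(2))

    def test_contact_limit_magnitude(self, params, geometry):
        # Video-parameter limit: Cr/lr - Ca/la = 1.1 - 1/7.5
        state = AgentState(np.array([[10.0, 10.0], [10.0 + 1e-6, 10.0]]),
                           np.zeros((2, 2)))
        f = social_force(1, state, np.array([0]), params, geometry)
        assert np.linalg.norm(f) == pytest.approx(1.1 - 1.0 / 7.5, rel=1e-4)
        assert f[0] > 0  # repulsive: pushes agent 1 away from agent 0

    def test_sign_change_at_balance_distance(self, params):
        d_star = force_balance_distance(params)
        assert d_star == pytest.approx(np.log(8.25) / (1 - 1 / 7.5), rel=1e-12)
        assert pair_force_coeff(d_star - 1e-6, params) > 0
        assert pair_force_coeff(d_star + 1e-6, params) < 0
        assert pair_force_coeff(d_star, params) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_oracle(self, params):
        # force coefficient equals -dU/dd by central differences
        h = 1e-6
        for d in np.linspace(0.1, 30.0, 97):
            numeric = -(pair_potential(d + h, params) - pair_potential(d - h, params)) / (2 * h)
            assert pair_force_coeff(d, params) == pytest.approx(numeric, rel=1e-6)

    def test_pair_forces_antisymmetric(self, params, geometry):
        state = AgentState(np.array([[10.0, 10.0], [14.0, 13.0]]), np.zeros((2, 2)))
        f0 = social_force(0, state, np.array([1]), params, geometry)
        f1 = social_force(1, state, np.array([0]), params, geometry)
        np.testing.assert_allclose(f0, -f1)

    def test_coincident_agents_contribute_nothing(self, params, geometry):
        state = AgentState(np.array([[10.0, 10.0], [10.0, 10.0]]), np.zeros((2, 2)))
        f = social_force(0, state, np.array([1]), params, geometry)
        np.testing.assert_array_equal(f, np.zeros(2))


class TestResponseAndAutonomousForce:
    @pytest.mark.parametrize(
        "psi0, psi1, s, expected",
        [(3.0, 2.54, 0.0, 3.0), (3.0, 2.45, 10.0, -21.5), (5.0, 0.0, 99.0, 5.0)],
    )
    def test_response_speed_param(self, psi0, psi1, s, expected):
        assert response_speed_param(psi0, psi1, s) == pytest.approx(expected)

    def test_zero_at_preferred_speed(self, params):
        v = np.array([np.sqrt(3.0), 0.0])  # eta |v|^2 = 3
        np.testing.assert_allclose(autonomous_force(3.0, v, params), np.zeros(2), atol=1e-12)

    def test_acceleration_along_heading(self, params):
        np.testing.assert_allclose(
            autonomous_force(3.0, np.array([1.0, 0.0]), params), [2.0, 0.0])

    def test_negative_psi_decelerates(self, params):
        v = np.array([0.3, 0.4])
        f = autonomous_force(-1.0, v, params)
        assert np.dot(f, v) < 0

    def test_zero_velocity_gives_zero_force(self, params):
        np.testing.assert_array_equal(autonomous_force(5.0, np.zeros(2), params), np.zeros(2))


class TestStep:
    def lone_agent(self, psi0, speed=1.5, gamma=0.0):
        geom = TorusGeometry(200.0)
        params = SocialParams(noise_magnitude=gamma)
        state = AgentState(np.array([[100.0, 100.0]]), np.array([[speed, 0.0]]))
        traits = Traits.uniform(1, psi0, 0.0, 30.0)
        return state, traits, params, geom

    def test_negative_psi_speed_decreases_monotonically(self):
        state, traits, params, geom = self.lone_agent(-0.5)
        rng = np.random.default_rng(0)
        speeds = [state.speeds[0]]
        for _ in range(30):
            state, _ = step(state, traits, params, None, rng, geom)
            speeds.append(state.speeds[0])
        assert all(b <= a + 1e-12 for a, b in zip(speeds, speeds[1:]))
        assert speeds[-1] == pytest.approx(0.0, abs=1e-9)

    def test_positive_psi_converges_to_fixed_point(self):
        state, traits, params, geom = self.lone_agent(2.5, speed=0.3)
        rng = np.random.default_rng(0)
        for _ in range(200):
            state, _ = step(state, traits, params, None, rng, geom)
        assert state.speeds[0] == pytest.approx(np.sqrt(2.5), rel=1e-6)

    def test_noise_magnitude_is_exact(self):
        geom = TorusGeometry(200.0)
        params = SocialParams(noise_magnitude=0.01)
        state = AgentState(np.array([[100.0, 100.0]]), np.zeros((1, 2)))
        traits = Traits.uniform(1, 0.0, 0.0, 30.0)
        new, _ = step(state, traits, params, None, np.random.default_rng(3), geom)
        assert new.speeds[0] == pytest.approx(0.01, rel=1e-12)

    def test_determinism_and_torus_equivariance(self, params):
        geom = TorusGeometry(80.0)
        rng_a = np.random.default_rng(11)
        state = random_state(np.random.default_rng(4), 25, geom)
        traits = Traits.uniform(25, 2.0, 0.0, 30.0)

        a = state.copy()
        for _ in range(20):
            a, _ = step(a, traits, params, None, rng_a, geom)

        # identical seed: identical trajectory
        rng_b = np.random.default_rng(11)
        b = state.copy()
        for _ in range(20):
            b, _ = step(b, traits, params, None, rng_b, geom)
        np.testing.assert_array_equal(a.positions, b.positions)

        # translated initial condition: translated trajectory
        shift = np.array([31.7, 55.2])
        rng_c = np.random.default_rng(11)
        c = AgentState(geom.wrap(state.positions + shift), state.velocities.copy())
        for _ in range(20):
            c, _ = step(c, traits, params, None, rng_c, geom)
        np.testing.assert_allclose(c.positions, geom.wrap(a.positions + shift), atol=1e-8)
        np.testing.assert_allclose(c.velocities, a.velocities, atol=1e-8)

    def test_station_keeping_threshold(self):
        # asymptotic speed is zero iff Psi <= 0 (algebraic 1/t decay exactly at 0)
        for psi, expect_moving in [(-0.4, False), (-0.05, False), (0.0, False),
                                   (0.05, True), (0.5, True)]:
            state, traits, params, geom = self.lone_agent(psi, speed=1.0)
            rng = np.random.default_rng(0)
            for _ in range(300):
                state, _ = step(state, traits, params, None, rng, geom)
            if expect_moving:
                assert state.speeds[0] == pytest.approx(np.sqrt(psi), rel=1e-3)
            elif psi == 0.0:
                # ds/dt = -s^2  =>  s(t) = s0 / (1 + s0 t)
                assert state.speeds[0] == pytest.approx(1.0 / 301.0, rel=0.05)
            else:
                assert state.speeds[0] < 1e-9  # arrested in finite time

    def test_reports_resource_at_step_start(self, rng):
        from swarmevo.environment import ResourcePeak, ResourceField

        geom = TorusGeometry(200.0)
        field = ResourceField([ResourcePeak(np.array([100.0, 100.0]), 10.0, 20.0)],
                              geometry=geom, drift=np.zeros(2), diffusion_sd=0.0)
        state = AgentState(np.array([[100.0, 100.0]]), np.array([[1.0, 0.0]]))
        traits = Traits.uniform(1, 1.0, 0.1, 30.0)
        _, s = step(state, traits, SocialParams(noise_magnitude=0.0), field, rng, geom)
        assert s[0] == pytest.approx(10.0)


class TestInteractionGraph:
    def test_isolated_agents_are_singletons(self, params):
        geom = TorusGeometry(400.0)
        state = AgentState(np.array([[10.0, 10.0], [200.0, 10.0], [10.0, 200.0]]),
                           np.zeros((3, 2)))
        traits = Traits.uniform(3, 1.0, 0.0, 30.0)
        _, comps = interaction_graph(state, traits, params, geom)
        assert sorted(len(c) for c in comps) == [1, 1, 1]

    def test_chain_is_one_group(self, params):
        geom = TorusGeometry(400.0)
        pos = np.column_stack([10.0 + 20.0 * np.arange(6), np.full(6, 10.0)])
        state = AgentState(pos, np.zeros((6, 2)))
        traits = Traits.uniform(6, 1.0, 0.0, 25.0)
        _, comps = interaction_graph(state, traits, params, geom)
        assert len(comps) == 1 and len(comps[0]) == 6

    def test_one_sided_influence_still_makes_edge(self):
        # with k=1, C's nearest is B; B's nearest is A; edge B-C exists anyway
        geom = TorusGeometry(400.0)
        params = SocialParams(neighbor_count=1)
        state = AgentState(np.array([[10.0, 10.0], [12.0, 10.0], [15.0, 10.0]]),
                           np.zeros((3, 2)))
        traits = Traits.uniform(3, 1.0, 0.0, 30.0)
        g, comps = interaction_graph(state, traits, params, geom)
        assert g.has_edge(1, 2)
        assert len(comps) == 1
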