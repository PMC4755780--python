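import numpy as np
import pandas as pd
import pytest

from conftest import random_state
from swarmevo.analysis import (
    SweepResult,
    classify_state,
    fit_arrival,
    group_peak_matching,
    kl_divergence_to_resource,
    mean_dist_knn,
    phase_boundary,
    phase_sweep,
    potential_energy,
    transition_edges,
)
from swarmevo.dynamics import AgentState, SocialParams, Traits, force_balance_distance
from swarmevo.environment import ResourceField, ResourcePeak
from swarmevo.fixtures import synth_counts
from swarmevo.geometry import TorusGeometry


def brute_mean_dknn(positions, geometry, k=10):
    d = geometry.pairwise_distances(positions)
    n = positions.shape[0]
    vals = []
    for i in range(n):
        others = np.delete(d[i], i)
        vals.append(np.sort(others)[:k].mean())
    return float(np.mean(vals))


class TestMeanDistKnn:
    def test_coincident_agents(self, geometry):
        pos = np.full((15, 2), 5.0)
        assert mean_dist_knn(pos, geometry) == 0.0

    def test_matches_brute_force_on_ring(self):
        geom = TorusGeometry(1000.0)
        theta = np.linspace(0, 2 * np.pi, 11, endpoint=False)
        pos = 500.0 + 8.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        assert mean_dist_knn(pos, geom) == pytest.approx(brute_mean_dknn(pos, geom))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random(self, seed):
        geom = TorusGeometry(70.0)
        rng = np.random.default_rng(seed)
        pos = geom.uniform(rng, 40)
        assert mean_dist_knn(pos, geom) == pytest.approx(brute_mean_dknn(pos, geom))

    def test_homogeneity(self):
        geom = TorusGeometry(4000.0)
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 100, size=(30, 2))
        a = mean_dist_knn(pos, geom)
        b = mean_dist_knn(pos * 2.0, geom)
        assert b == pytest.approx(2 * a, rel=1e-9)

    def test_too_few_agents_rejected(self, geometry):
        with pytest.raises(ValueError):
            mean_dist_knn(np.zeros((10, 2)), geometry)


class TestPotentialEnergy:
    def test_no_neighbors_zero(self, params):
        geom = TorusGeometry(500.0)
        state = AgentState(np.array([[10.0, 10.0], [300.0, 300.0]]), np.zeros((2, 2)))
        traits = Traits.uniform(2, 1.0, 0.0, 30.0)
        assert potential_energy(state, traits, params, geom) == 0.0

    def test_pair_at_balance_distance(self, params):
        geom = TorusGeometry(500.0)
        d_star = force_balance_distance(params)
        state = AgentState(np.array([[10.0, 10.0], [10.0 + d_star, 10.0]]),
                           np.zeros((2, 2)))
        traits = Traits.uniform(2, 1.0, 0.0, 30.0)
        expected = 1.1 * np.exp(-d_star) - 1.0 * np.exp(-d_star / 7.5)
        assert potential_energy(state, traits, params, geom) == pytest.approx(expected)

    def test_packed_higher_than_dispersed(self, params, rng):
        geom = TorusGeometry(500.0)
        traits = Traits.uniform(20, 1.0, 0.0, 30.0)
        # contact-range packing, where the repulsive term dominates the potential
        tight = AgentState(250 + rng.uniform(0, 0.05, (20, 2)), np.zeros((20, 2)))
        loose = AgentState(geom.uniform(rng, 20), np.zeros((20, 2)))
        assert (potential_energy(tight, traits, params, geom)
                > potential_energy(loose, traits, params, geom))


class TestClassifyState:
    @pytest.mark.parametrize("psi, label", [(-0.5, "station-keeping"), (0.0, "station-keeping"),
                                            (1.0, "cohesive"), (2.95, "cohesive"),
                                            (3.0, "dispersed")])
    def test_examples(self, psi, label):
        assert classify_state(np.array([psi]))[0] == label

    def test_partitions_real_line(self):
        grid = np.linspace(-5, 8, 1001)
        labels = classify_state(grid)
        changes = np.nonzero(labels[1:] != labels[:-1])[0]
        assert len(changes) == 2  # exactly the two thresholds


class TestKLDivergence:
    def field(self, lam0=10.0, lam1=10.0, L=200.0):
        return ResourceField([ResourcePeak(np.array([L / 2, L / 2]), lam0, lam1)],
                             geometry=TorusGeometry(L), drift=np.zeros(2),
                             diffusion_sd=0.0)

    def test_matched_distribution_near_zero(self, rng):
        field = self.field()
        # sample many agents from the resource distribution (2-D gaussian, sd lam1/sqrt(2))
        pos = 100.0 + rng.normal(0, 10.0 / np.sqrt(2), size=(20000, 2))
        kl = kl_divergence_to_resource(pos, field)
        assert kl < 0.01

    def test_concentrated_agents_positive(self):
        field = self.field()
        pos = np.full((50, 2), 100.0) + np.array([12.0, 0.0])  # one annulus only
        assert kl_divergence_to_resource(pos, field) > 0.5

    def test_direct_summation_oracle(self, rng):
        field = self.field()
        pos = 100.0 + rng.normal(0, 9.0, size=(500, 2))
        kl = kl_divergence_to_resource(pos, field)
        # independent direct computation
        peak = field.peaks[0]
        edges = np.linspace(0, 30.0, 31)
        r = field.geometry.distance(np.atleast_2d(pos), peak.centroid)
        q, _ = np.histogram(r, bins=edges)
        shell = np.exp(-edges[:-1] ** 2 / 100.0) - np.exp(-edges[1:] ** 2 / 100.0)
        p = peak.amplitude * np.pi * 100.0 * shell + 1e-9
        q = q + 1e-9
        p = p / p.sum()
        q = q / q.sum()
        direct = float(np.sum(p * np.log(p / q)))
        assert kl == pytest.approx(direct, rel=1e-9)

    def test_no_agents_in_range_rejected(self):
        field = self.field(L=400.0)
        pos = np.full((5, 2), 10.0)  # hundreds of units from the peak
        with pytest.raises(ValueError):
            kl_divergence_to_resource(pos, field)


class TestArrivalFits:
    def test_flat_series_degenerate(self):
        curve = fit_arrival(np.arange(50.0), np.full(50, 7.0))
        assert curve.degenerate and curve.preferred is None

    def test_exponential_recovery_noise_free(self):
        t, y = synth_counts("exponential", {"kappa_s1": 5.0, "kappa_s2": 0.01}, 0.0, 400)
        curve = fit_arrival(t, y)
        assert curve.preferred == "exponential"
        assert curve.exponential["kappa_s1"] == pytest.approx(5.0, rel=0.01)
        assert curve.exponential["kappa_s2"] == pytest.approx(0.01, rel=0.01)

    def test_linear_recovery_noise_free(self):
        t, y = synth_counts("linear", {"kappa_a": 0.5, "intercept": 2.0}, 0.0, 200)
        curve = fit_arrival(t, y)
        assert curve.preferred == "linear"
        assert curve.linear["kappa_a"] == pytest.approx(0.5, rel=1e-6)

    def test_model_selection_under_noise(self):
        # generating model recovered in >= 95% of seeded replicates
        hits = 0
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t, y = synth_counts("exponential", {"kappa_s1": 5.0, "kappa_s2": 0.012},
                                2.0, 400, rng)
            hits += fit_arrival(t, y).preferred == "exponential"
            total += 1
            rng = np.random.default_rng(1000 + seed)
            t, y = synth_counts("linear", {"kappa_a": 0.3, "intercept": 5.0}, 2.0, 400, rng)
            hits += fit_arrival(t, y).preferred == "linear"
            total += 1
        assert hits / total >= 0.95


class TestGroupPeakMatching:
    def two_peak_field(self, L=200.0, amps=(10.0, 5.0), lam1=10.0):
        peaks = [ResourcePeak(np.array([L / 4, L / 2]), amps[0], lam1),
                 ResourcePeak(np.array([3 * L / 4, L / 2]), amps[1], lam1)]
        return ResourceField(peaks, geometry=TorusGeometry(L), drift=np.zeros(2),
                             diffusion_sd=0.0)

    def test_single_cluster_is_full_population(self, params, rng):
        field = self.two_peak_field(amps=(10.0, 0.0))
        pos = field.peaks[0].centroid + rng.uniform(-2, 2, size=(30, 2))
        state = AgentState(pos, np.zeros((30, 2)))
        traits = Traits.uniform(30, 1.0, 0.0, 30.0)
        table = group_peak_matching([state], traits, params, field)
        assert table["mean_group_size"].iloc[0] == 30

    def test_two_clusters_match_their_peaks(self, params, rng):
        field = self.two_peak_field()
        p0, p1 = (p.centroid for p in field.peaks)
        pos = np.vstack([p0 + rng.uniform(-2, 2, size=(20, 2)),
                         p1 + rng.uniform(-2, 2, size=(10, 2))])
        state = AgentState(pos, np.zeros((30, 2)))
        traits = Traits.uniform(30, 1.0, 0.0, 10.0)
        table = group_peak_matching([state], traits, params, field)
        assert table["mean_group_size"].tolist() == [20.0, 10.0]
        assert table["peak_mass"].iloc[0] == pytest.approx(2 * table["peak_mass"].iloc[1])


class TestSweeps:
    def test_transition_edges_locate_jumps(self):
        grid_down = np.array([3.0, 2.5, 2.0, 1.5, 1.0])
        down = SweepResult("Psi", grid_down, "decreasing",
                           np.array([[18.0], [17.5], [4.0], [2.0], [1.8]]))
        up = SweepResult("Psi", grid_down[::-1], "increasing",
                         np.array([[1.8], [2.0], [2.4], [17.0], [18.0]]))
        lower, upper = transition_edges(down, up)
        assert lower == pytest.approx(2.0)
        assert upper == pytest.approx(2.5)

    def test_phase_sweep_without_interactions_is_ideal_gas(self):
        # k = 0: no social forces; density stays that of uniform random points
        geom = TorusGeometry(60.0)
        rng = np.random.default_rng(8)
        df = phase_sweep("k", np.array([0]), np.array([0.5, 3.0]), SocialParams(),
                         n_agents=60, rng=rng, steps=150, geometry=geom)
        reference = np.mean([
            mean_dist_knn(geom.uniform(np.random.default_rng(100 + i), 60), geom)
            for i in range(40)
        ])
        for _, row in df.iterrows():
            assert row["d10nn"] == pytest.approx(reference, rel=0.15)

    def test_phase_boundary_finds_steepest_rise(self):
        df = pd.DataFrame({
            "param_value": 1.0,
            "psi0": [0.5, 1.0, 1.5, 2.0],
            "replicate": 0,
            "d10nn": [2.0, 2.2, 15.0, 16.0],
        })
        b = phase_boundary(df)
        assert b["psi0_boundary"].iloc[0] == pytest.approx(1.25)
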