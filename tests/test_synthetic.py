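"""Synthetic-cohort generator: planted networks, BOLD model, cohort structure."""

import numpy as np
import pytest
from scipy import stats

from netnorm import (
    BoldTimeSeries,
    SyntheticCohortSpec,
    generate_cohort,
    generate_labeled_mesh,
    generate_planted_network,
    simulate_bold,
)
from netnorm.connectivity import timeseries_to_network
from netnorm.metrics import characteristic_path_length
from netnorm.synthetic import (
    draw_cohort_latents,
    implied_correlation_matrix,
    weighted_erdos_renyi,
)


def two_node_network(weight):
    from netnorm import WeightedNetwork

    a = np.array([[0.0, weight], [weight, 0.0]])
    return WeightedNetwork(a)


class TestPlantedNetworks:
    def test_beta_zero_is_a_ring_lattice(self):
        net = generate_planted_network(10, 4, beta=0.0, weight_law="unit", seed=0)
        assert np.array_equal(net.degrees(), np.full(10, 4))
        # nearest and next-nearest ring neighbors only
        for i in range(10):
            for j in range(10):
                expected = min((i - j) % 10, (j - i) % 10) in (1, 2)
                assert (net.adjacency[i, j] > 0) == expected

    def test_full_rewiring_conserves_degree_sum(self):
        net = generate_planted_network(10, 4, beta=1.0, seed=1)
        assert net.degrees().sum() == 40

    def test_weights_respect_the_weight_range(self):
        net = generate_planted_network(30, 6, 0.3, seed=2, weight_range=(0.2, 1.0))
        _, _, w = net.edge_array()
        assert w.min() >= 0.2 and w.max() <= 1.0

    def test_lattice_clustering_follows_closed_form(self):
        # mean unweighted clustering over 100 seeds ~ 3(k-2)/(4(k-1)) (1-b)^3
        k, beta = 10, 0.1
        lattice_c = 3 * (k - 2) / (4 * (k - 1))
        expected = lattice_c * (1 - beta) ** 3
        values = []
        for s in range(100):
            net = generate_planted_network(200, k, beta, weight_law="unit", seed=s)
            a = net.adjacency > 0
            # brute-force triangle counting per node
            deg = a.sum(axis=1)
            tri = np.diag(a.astype(float) @ a @ a)
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(deg >= 2, tri / (deg * (deg - 1)), 0.0)
            values.append(c.mean())
        assert 0.8 * expected < np.mean(values) < 1.2 * expected

    def test_determinism(self):
        a = generate_planted_network(50, 6, 0.3, seed=7).adjacency
        b = generate_planted_network(50, 6, 0.3, seed=7).adjacency
        assert np.array_equal(a, b)

    def test_hub_bias_skews_degree_distribution(self):
        plain = generate_planted_network(200, 6, 0.4, seed=8, hub_bias=0.0)
        hubby = generate_planted_network(200, 6, 0.4, seed=8, hub_bias=4.0)
        assert hubby.degrees().max() > plain.degrees().max()
        assert hubby.degrees().sum() == plain.degrees().sum()


class TestBoldSimulation:
    def test_unconnected_nodes_uncorrelated(self):
        # null sampling distribution of r at T=10000: |r| < 0.05 whp
        x = simulate_bold(two_node_network(0.0), 10000, noise_sd=1.0, seed=3)
        r = np.corrcoef(x)[0, 1]
        assert abs(r) < 0.05

    def test_deterministic_under_seed(self):
        net = generate_planted_network(20, 4, 0.2, seed=4)
        a = simulate_bold(net, 60, seed=5)
        b = simulate_bold(net, 60, seed=5)
        assert np.array_equal(a, b)

    def test_near_maximal_weight_gives_strong_correlation(self):
        net = two_node_network(0.98)
        implied = implied_correlation_matrix(net, noise_sd=0.2)[0, 1]
        assert implied > 0.5  # analytic value from the mixing model
        x = simulate_bold(net, 10000, noise_sd=0.2, seed=6)
        assert np.corrcoef(x)[0, 1] > 0.5

    def test_correlation_increases_with_edge_weight(self):
        net = generate_planted_network(60, 6, 0.2, seed=9)
        implied = implied_correlation_matrix(net, noise_sd=0.3)
        iu, iv, w = net.edge_array()
        res = stats.spearmanr(w, implied[iu, iv])
        # strongly positive rank relation (endpoint strengths and shared
        # neighbors add edge-to-edge variation around the monotone trend)
        assert res.statistic > 0.3
        assert res.pvalue < 1e-6


class TestCohorts:
    def test_cohort_reproducible(self):
        spec = SyntheticCohortSpec(n_subjects=4, node_count_mean=40, node_count_sd=4, seed=11)
        c1 = generate_cohort(spec)
        c2 = generate_cohort(spec)
        for a, b in zip(c1.subjects, c2.subjects):
            assert np.array_equal(a.timeseries.matrix, b.timeseries.matrix)
            assert a.outcome == b.outcome

    def test_null_effect_size_gives_uniform_association(self):
        # with effect_size = 0 the outcome/beta correlation test should be
        # non-significant in >= 90% of 100 replicate cohorts at n=26
        nonsig = 0
        for s in range(100):
            spec = SyntheticCohortSpec(effect_size=0.0, seed=s)
            lat = draw_cohort_latents(spec)
            p = stats.pearsonr(lat["outcome"], lat["beta"]).pvalue
            nonsig += p > 0.05
        assert nonsig >= 90

    def test_node_count_correlates_with_age(self):
        spec = SyntheticCohortSpec(n_subjects=100, seed=12)
        lat = draw_cohort_latents(spec)
        r = stats.pearsonr(lat["age"], lat["z_node"]).statistic
        assert r > 0.3  # positive, mirroring cortical volume vs age

    def test_outcome_independent_of_node_count_given_beta(self):
        spec = SyntheticCohortSpec(n_subjects=400, seed=13)
        lat = draw_cohort_latents(spec)
        # outcome is a function of beta + noise; z_node enters nowhere
        resid = lat["outcome"] - lat["signal"]
        assert abs(stats.pearsonr(resid, lat["z_node"]).statistic) < 0.15

    def test_planted_r2_recorded_and_large_enough(self):
        spec = SyntheticCohortSpec(n_subjects=26, node_count_mean=40, node_count_sd=3, seed=14)
        cohort = generate_cohort(spec)
        assert cohort.metadata["planted_r2"] >= 0.3

    @staticmethod
    def _pooled_length_count_corr(true_resolution, n_cohorts=3):
        lengths, counts = [], []
        for seed in range(n_cohorts):
            spec = SyntheticCohortSpec(true_resolution=true_resolution, seed=900 + seed)
            cohort = generate_cohort(spec)
            for s in cohort.subjects:
                net = timeseries_to_network(s.timeseries)
                lengths.append(characteristic_path_length(net))
                counts.append(s.covariates["n_nodes"])
        return stats.pearsonr(lengths, counts).statistic

    def test_raw_path_length_is_scale_confounded(self):
        """The defining property: raw path length correlates with node count.

        The size/SNR coupling alone drives |r| well above 0.3 (measured
        with the parcel-heterogeneity penalty switched off by declaring the
        default scale the finest one); with the penalty active at the
        default scale its extra nuisance variance dilutes the coefficient,
        but the association stays positive.
        """
        assert self._pooled_length_count_corr(true_resolution=420) > 0.3
        assert self._pooled_length_count_corr(true_resolution=1620) > 0.0

    def test_degenerate_sd_with_confound_warns(self):
        with pytest.warns(UserWarning):
            SyntheticCohortSpec(node_count_sd=0.0, covariate_confound_strength=0.5)


class TestMeshes:
    def test_flat_grid_area_exact(self):
        mesh, labels = generate_labeled_mesh((10, 10), 1.0)
        assert mesh.total_area() == pytest.approx(100.0)
        assert len(labels) == 121 and set(labels) == {0}

    def test_two_by_two_grid_triangles(self):
        mesh, _ = generate_labeled_mesh((2, 2), 1.0)
        assert len(mesh.faces) == 8
        assert np.allclose(mesh.face_areas(), 0.5)

    def test_strip_longest_axis_runs_along_length(self):
        from netnorm import longest_axis

        mesh, labels = generate_labeled_mesh((40, 10), 1.0)
        (vi, vj), axis = longest_axis(mesh, np.arange(mesh.n_vertices))
        assert abs(axis[0]) >= 39.0  # along the 40-cell direction

    def test_strip_layout_covers_all_vertices(self):
        mesh, labels = generate_labeled_mesh((12, 4), 1.0, parcel_layout=3)
        assert len(set(labels)) == 3
        assert len(labels) == mesh.n_vertices


class TestErdosRenyi:
    def test_density_close_to_p(self):
        net = weighted_erdos_renyi(200, 0.1, seed=30)
        density = 2 * net.n_edges / (200 * 199)
        assert 0.08 < density < 0.12
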