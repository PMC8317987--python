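import numpy as np
import pytest

from lbpnet import (
    DEFAULT_DENSITIES,
    BinaryGraph,
    betweenness_centrality,
    clustering_coefficient,
    degree_centrality,
    local_efficiency,
    metrics_across_densities,
    threshold_by_density,
)

from _oracles import (
    betweenness_oracle,
    clustering_oracle,
    degree_oracle,
    local_efficiency_oracle,
    random_graph,
)


def adjacency(edges, n):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


TRIANGLE = adjacency([(0, 1), (1, 2), (0, 2)], 3)
PATH3 = adjacency([(0, 1), (1, 2)], 3)
STAR5 = adjacency([(0, i) for i in range(1, 6)], 6)
STAR4 = adjacency([(0, i) for i in range(1, 5)], 5)
K4 = adjacency([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)
CYCLE5 = adjacency([(i, (i + 1) % 5) for i in range(5)], 5)
# square A-B-C-D-A plus diagonal A-C (A=0, B=1, C=2, D=3)
SQUARE_DIAG = adjacency([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)], 4)
K4_MINUS_CD = adjacency([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)], 4)
EMPTY4 = np.zeros((4, 4), dtype=int)


class TestThresholding:
    def test_edge_count_at_density(self, rng):
        fc = rng.standard_normal((10, 10))
        fc = (fc + fc.T) / 2
        g = threshold_by_density(fc, 0.20)
        assert g.adjacency.sum() // 2 == 9  # 0.20 * 45

    def test_all_equal_weights_tie_rule(self):
        w = np.ones((10, 10))
        np.fill_diagonal(w, np.nan)
        g = threshold_by_density(w, 0.15)
        assert g.adjacency.sum() // 2 == 7  # round(6.75) half-up
        # first 7 edges in (i, j) lexicographic order
        iu, ju = np.triu_indices(10, 1)
        expected = np.zeros((10, 10), dtype=int)
        for i, j in zip(iu[:7], ju[:7]):
            expected[i, j] = expected[j, i] = 1
        assert np.array_equal(g.adjacency, expected)

    def test_distinct_integer_weights_sort_cut(self):
        n = 10
        iu, ju = np.triu_indices(n, 1)
        w = np.zeros((n, n))
        weights = np.arange(1, 46)
        w[iu, ju] = weights
        w = w + w.T
        g = threshold_by_density(w, 0.20)
        kept = g.adjacency[iu, ju].astype(bool)
        assert set(weights[kept]) == set(range(37, 46))

    def test_degenerate_density_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            threshold_by_density(np.ones((4, 4)), 0.05)
        with pytest.raises(ValueError, match="density"):
            threshold_by_density(np.ones((4, 4)), 1.5)

    def test_nested_edge_sets_and_dc_monotonicity(self, rng):
        fc = rng.standard_normal((20, 20))
        fc = (fc + fc.T) / 2
        prev = None
        for d in DEFAULT_DENSITIES:
            g = threshold_by_density(fc, d).adjacency
            if prev is not None:
                assert np.all(prev <= g)  # edge sets nest
                assert np.all(degree_centrality(prev) <= degree_centrality(g))
            prev = g

    def test_isomorphism_invariance(self, rng):
        fc = rng.standard_normal((12, 12))
        fc = (fc + fc.T) / 2
        perm = rng.permutation(12)
        g = threshold_by_density(fc, 0.25).adjacency
        # permuted FC may re-break ties differently only when weights tie;
        # continuous weights are a.s. distinct, so metrics must permute
        gp = threshold_by_density(fc[np.ix_(perm, perm)], 0.25).adjacency
        for metric in (degree_centrality, clustering_coefficient,
                       betweenness_centrality, local_efficiency):
            assert np.allclose(metric(gp), metric(g)[perm], atol=1e-9)


class TestMetricExamples:
    @pytest.mark.parametrize(
        "adj,expected",
        [
            (TRIANGLE, [2, 2, 2]),
            (STAR5, [5, 1, 1, 1, 1, 1]),
            (EMPTY4, [0, 0, 0, 0]),
        ],
    )
    def test_degree(self, adj, expected):
        assert np.array_equal(degree_centrality(adj), expected)

    @pytest.mark.parametrize(
        "adj,expected",
        [
            (K4, [1, 1, 1, 1]),
            (STAR5, [0] * 6),
            # hand count: A's neighbors {B, C, D} have 2 of 3 pairs linked
            (SQUARE_DIAG, [2 / 3, 1, 2 / 3, 1]),
        ],
    )
    def test_clustering(self, adj, expected):
        assert np.allclose(clustering_coefficient(adj), expected)

    @pytest.mark.parametrize(
        "adj,expected",
        [
            (PATH3, [0, 1, 0]),
            (STAR4, [6, 0, 0, 0, 0]),  # C(4,2) leaf pairs through the hub
            # each node is interior to exactly one distance-2 pair
            (CYCLE5, [1.0] * 5),
        ],
    )
    def test_betweenness(self, adj, expected):
        assert np.allclose(betweenness_centrality(adj), expected)

    @pytest.mark.parametrize(
        "adj,expected",
        [
            (TRIANGLE, [1, 1, 1]),
            (STAR5, [0] * 6),
            (K4_MINUS_CD, [5 / 6, 5 / 6, 1, 1]),
        ],
    )
    def test_local_efficiency(self, adj, expected):
        assert np.allclose(local_efficiency(adj), expected)


class TestBinaryGraphValidation:
    def test_rejects_asymmetric(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            BinaryGraph(a, density=0.1)

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            BinaryGraph(np.eye(3, dtype=int), density=0.1)


class TestBruteForceEquivalence:
    def test_all_metrics_match_oracles_on_random_graphs(self):
        rng = np.random.default_rng(7)
        pairs = [
            (degree_centrality, degree_oracle),
            (clustering_coefficient, clustering_oracle),
            (betweenness_centrality, betweenness_oracle),
            (local_efficiency, local_efficiency_oracle),
        ]
        for _ in range(30):
            a = random_graph(rng, n_max=8)
            for impl, oracle in pairs:
                assert np.allclose(impl(a), oracle(a), atol=1e-9)


class TestMetricsAcrossDensities:
    def test_single_density_equals_direct_metrics(self, rng):
        fc = rng.standard_normal((12, 12))
        fc = (fc + fc.T) / 2
        tab = metrics_across_densities(fc, densities=(0.2,))
        g = threshold_by_density(fc, 0.2)
        assert np.allclose(tab["DC"], degree_centrality(g))
        assert np.allclose(tab["BC"], betweenness_centrality(g))

    def test_mean_matches_naive_loop(self, rng):
        fc = rng.standard_normal((12, 12))
        fc = (fc + fc.T) / 2
        tab = metrics_across_densities(fc)
        for name, fn in [
            ("DC", degree_centrality),
            ("CC", clustering_coefficient),
            ("BC", betweenness_centrality),
            ("LE", local_efficiency),
        ]:
            acc = np.zeros(12)
            for d in DEFAULT_DENSITIES:
                acc += fn(threshold_by_density(fc, d))
            assert np.allclose(tab[name], acc / len(DEFAULT_DENSITIES), atol=1e-12)

    def test_rejects_bad_grid(self, rng):
        fc = rng.standard_normal((6, 6))
        with pytest.raises(ValueError, match="increasing"):
            metrics_across_densities(fc, densities=(0.3, 0.2))
        with pytest.raises(ValueError, match="unknown metric"):
            metrics_across_densities(fc, metrics=("DC", "XX"))
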