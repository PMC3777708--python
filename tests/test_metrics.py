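"""Thresholding, binary graph metrics, rewiring nulls, sparsity curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import synconn as sc
from synconn.exceptions import DataError, DisconnectedGraphError
from synconn.metrics import BinaryGraph, GlobalMetricSet, MetricCurve

from oracle_graphs import (
    critical_r_bruteforce,
    oracle_betweenness,
    oracle_clustering,
    oracle_cpl,
    oracle_participation,
    random_connected_graph,
)


def graph_from_edges(n, edges, sparsity=0.5):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(adjacency=adj, sparsity=sparsity)


def random_weights(n, rng):
    w = rng.normal(0.2, 0.5, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


class TestThreshold:
    def test_keeps_exactly_the_strongest_positive_edges(self):
        rng = np.random.default_rng(0)
        w = random_weights(5, rng)
        g = sc.threshold_to_sparsity(w, 0.2)  # 10 pairs -> 2 edges
        assert g.n_edges == 2
        iu = np.triu_indices(5, 1)
        top2 = np.sort(w[iu])[::-1][:2]
        kept = np.sort(w[g.adjacency & np.triu(np.ones((5, 5), bool), 1)])[::-1]
        assert np.allclose(kept, top2)

    def test_all_negative_weights_is_an_error(self):
        w = -np.ones((6, 6))
        np.fill_diagonal(w, 0)
        with pytest.raises(DataError, match="maximum achievable sparsity"):
            sc.threshold_to_sparsity(w, 0.1)

    def test_tie_break_is_deterministic_and_lexicographic(self):
        n = 6
        w = np.full((n, n), 0.5)
        np.fill_diagonal(w, 0.0)
        g1 = sc.threshold_to_sparsity(w, 0.2)  # 15 pairs -> 3 edges, all tied
        g2 = sc.threshold_to_sparsity(w, 0.2)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        kept = sorted(zip(*np.nonzero(np.triu(g1.adjacency, 1))))
        assert kept == [(0, 1), (0, 2), (0, 3)]

    def test_quota_matches_rounding_rule(self):
        rng = np.random.default_rng(3)
        w = np.abs(random_weights(9, rng)) + 0.01
        for s in (0.1, 0.25, 0.5):
            g = sc.threshold_to_sparsity(w, s)
            assert g.n_edges == int(np.floor(s * 36 + 0.5))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_edge_sets_are_nested_across_sparsities(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weights(12, rng)
        # perturb to avoid ties so nestedness is strict
        w += rng.normal(0, 1e-9, w.shape)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        try:
            g1 = sc.threshold_to_sparsity(w, 0.15)
            g2 = sc.threshold_to_sparsity(w, 0.35)
        except DataError:
            return  # not enough positive weights at this draw
        assert np.all(~g1.adjacency | g2.adjacency)
        assert sc.count_components(g1) >= sc.count_components(g2)


class TestSimpleMetrics:
    def test_component_counts(self):
        n = 7
        assert sc.count_components(graph_from_edges(n, [])) == n
        path = graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])
        assert sc.count_components(path) == 1

    def test_clustering_examples(self):
        tri = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        vals, mean = sc.clustering_coefficient(tri)
        assert np.allclose(vals, 1.0) and mean == 1.0
        star = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        vals, mean = sc.clustering_coefficient(star)
        assert np.allclose(vals, 0.0)
        # 4-cycle with one chord: nodes on the chord have cc 1/3, others 1
        chord = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        _, mean = sc.clustering_coefficient(chord)
        assert mean == pytest.approx(5 / 6)

    def test_cpl_examples(self):
        k5 = graph_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        assert sc.characteristic_path_length(k5) == pytest.approx(1.0)
        p4 = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert sc.characteristic_path_length(p4) == pytest.approx(10 / 6)
        two = graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(DisconnectedGraphError):
            sc.characteristic_path_length(two)

    def test_betweenness_examples(self):
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        bc = sc.betweenness_centrality(star)
        assert bc[0] == pytest.approx(6.0)  # (n-1)(n-2)/2
        assert np.allclose(bc[1:], 0.0)
        k4 = graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert np.allclose(sc.betweenness_centrality(k4), 0.0)
        p3 = graph_from_edges(3, [(0, 1), (1, 2)])
        assert sc.betweenness_centrality(p3)[1] == pytest.approx(1.0)

    def test_participation_examples(self):
        part = sc.Partition(np.array([0, 0, 0, 1, 1]))
        inside = graph_from_edges(5, [(0, 1), (0, 2)])
        assert sc.participation_coefficient(inside, part)[0] == pytest.approx(0.0)
        split = graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        assert sc.participation_coefficient(split, part)[0] == pytest.approx(0.5)
        iso = graph_from_edges(5, [(1, 2)])
        assert sc.participation_coefficient(iso, part)[0] == 0.0


class TestOracleEquivalence:
    """CC, CPL, BC, PC agree with brute-force enumeration on small graphs."""

    def test_metrics_match_bruteforce_on_random_connected_graphs(self):
        rng = np.random.default_rng(42)
        labels_rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            adj = random_connected_graph(n, rng)
            g = BinaryGraph(adjacency=adj.astype(bool), sparsity=0.5)
            vals, _ = sc.clustering_coefficient(g)
            assert np.allclose(vals, oracle_clustering(adj))
            assert sc.characteristic_path_length(g) == pytest.approx(oracle_cpl(adj))
            assert np.allclose(sc.betweenness_centrality(g), oracle_betweenness(adj))
            labels = labels_rng.integers(0, 3, size=n)
            part = sc.Partition(labels)
            assert np.allclose(
                sc.participation_coefficient(g, part),
                oracle_participation(adj, part.labels),
            )


class TestRewiring:
    def test_degree_sequence_and_connectedness_preserved(self):
        rng = np.random.default_rng(1)
        w = random_weights(30, rng)
        g = sc.threshold_to_sparsity(w, 0.2)
        assert sc.count_components(g) == 1
        for trial in range(20):
            null = sc.rewire_preserving_degree(g, seed=trial)
            assert np.array_equal(null.degrees, g.degrees)
            assert sc.count_components(null) == 1

    def test_rewiring_is_seed_reproducible_and_changes_edges(self):
        rng = np.random.default_rng(2)
        g = sc.threshold_to_sparsity(random_weights(25, rng), 0.25)
        a = sc.rewire_preserving_degree(g, seed=9)
        b = sc.rewire_preserving_degree(g, seed=9)
        c = sc.rewire_preserving_degree(g, seed=10)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert not np.array_equal(a.adjacency, c.adjacency)
        assert not np.array_equal(a.adjacency, g.adjacency)

    def test_triangle_has_no_alternative_and_warns(self):
        tri = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.warns(UserWarning, match="unchanged"):
            out = sc.rewire_preserving_degree(tri, seed=0)
        assert np.array_equal(out.adjacency, tri.adjacency)


class TestNormalizedMetrics:
    def test_small_worldness_is_exactly_lambda_over_gamma(self):
        m = GlobalMetricSet(cc=0.5, cpl=2.0, lambda_=2.18, gamma=1.09,
                            small_worldness=2.18 / 1.09, q=0.4)
        assert m.small_worldness == m.lambda_ / m.gamma

    def test_random_graph_self_normalizes_to_one(self):
        # an Erdos-Renyi-like graph against its own rewired ensemble
        rng = np.random.default_rng(8)
        adj = (rng.random((40, 40)) < 0.25)
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        g = BinaryGraph(adjacency=adj, sparsity=float(adj.sum() / (40 * 39)))
        assert sc.count_components(g) == 1
        norm = sc.normalized_metrics(g, n_nulls=30, seed=4)
        assert 0.9 <= norm["lambda"] <= 1.1
        assert 0.9 <= norm["gamma"] <= 1.1
        assert norm["small_worldness"] == pytest.approx(norm["lambda"] / norm["gamma"])

    def test_zero_nulls_is_an_error(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        with pytest.raises(DataError):
            sc.normalized_metrics(g, n_nulls=0)


class TestMetricCurve:
    def _constant_curve(self, c):
        levels = tuple(
            GlobalMetricSet(cc=c, cpl=c, lambda_=c, gamma=c, small_worldness=c, q=c)
            for _ in range(5)
        )
        return MetricCurve(grid=np.linspace(0.1, 0.3, 5), levels=levels)

    def test_constant_curve_summaries_equal_the_constant(self):
        curve = self._constant_curve(0.7)
        assert all(v == pytest.approx(0.7) for v in curve.summary().values())
        assert all(v == pytest.approx(0.7) for v in curve.summary_integrated().values())

    def test_linear_curve_averages_to_midpoint(self):
        grid = np.linspace(0.1, 0.3, 5)
        levels = tuple(
            GlobalMetricSet(cc=s, cpl=s, lambda_=s, gamma=s, small_worldness=s, q=s)
            for s in grid
        )
        curve = MetricCurve(grid=grid, levels=levels)
        mid = float(grid.mean())
        assert curve.summary()["cc"] == pytest.approx(mid)
        assert curve.summary_integrated()["cc"] == pytest.approx(mid)

    def test_disconnected_level_is_reported(self):
        w = np.zeros((8, 8))
        # two positive cliques, no positive cross weights
        for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            w[a, b] = w[b, a] = 1.0
        with pytest.raises(DisconnectedGraphError) as err:
            sc.metric_curve(w, grid=np.array([0.1, 0.2]), n_nulls=2, n_louvain=2, seed=0)
        assert err.value.failing_levels


class TestCriticalCorrelation:
    def test_reproduces_the_printed_thresholds(self):
        assert sc.critical_correlation(120, 0.05, "one") == pytest.approx(0.15, abs=0.005)
        assert sc.critical_correlation(120, 0.05, "two") == pytest.approx(0.179, abs=0.005)

    def test_matches_bruteforce_inversion(self):
        assert sc.critical_correlation(20, 0.05, "two") == pytest.approx(
            critical_r_bruteforce(20, 0.05, "two"), abs=1e-4
        )

    def test_decreases_with_sample_size(self):
        vals = [sc.critical_correlation(n, 0.05, "one") for n in (10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.06

    def test_invalid_arguments(self):
        with pytest.raises(DataError):
            sc.critical_correlation(3, 0.05)
        with pytest.raises(DataError):
            sc.critical_correlation(20, 1.5)
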