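import networkx as nx
import numpy as np
import pytest

from spanet.data_model import interactome_from_edges
from spanet.errors import ParameterError
from spanet.tuning import (
    betweenness,
    control_chart,
    randomize,
    significance_test,
    tune,
)

from conftest import nx_from_adj
from _oracles import brute_betweenness, random_adjacency


class TestBetweenness:
    def test_path_graph_values(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        bc = betweenness(g)
        assert bc["c"] == pytest.approx(4.0)
        assert bc["b"] == pytest.approx(3.0)
        assert bc["a"] == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [4, 7, 11])
    def test_star_center_analytic(self, n):
        g = nx.star_graph(n)
        assert betweenness(g)[0] == pytest.approx(n * (n - 1) / 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        adj = random_adjacency(10, 0.3, seed)
        g = nx_from_adj(adj)
        bc = betweenness(g)
        oracle = brute_betweenness(adj)
        for v in adj:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)


class TestRandomize:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_preserved(self, seed):
        adj = random_adjacency(30, 0.15, seed)
        g = nx_from_adj(adj)
        h = randomize(g, swaps_per_edge=5, seed=seed)
        assert dict(h.degree) == dict(g.degree)
        assert not any(a == b for a, b in h.edges)

    def test_triangle_returned_unchanged_with_warning(self):
        g = interactome_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        with pytest.warns(UserWarning, match="no valid"):
            h = randomize(g, seed=0)
        assert nx.utils.graphs_equal(g, h)

    def test_deterministic_for_fixed_seed(self):
        g = nx_from_adj(random_adjacency(20, 0.2, 3))
        h1 = randomize(g, seed=42)
        h2 = randomize(g, seed=42)
        assert nx.utils.graphs_equal(h1, h2)

    def test_too_few_edges_rejected(self):
        with pytest.raises(ParameterError):
            randomize(interactome_from_edges([("A", "B")]))


class TestSignificanceTest:
    def test_permanent_leaf_discarded(self):
        # a node whose BC is always zero carries no information flow
        res = significance_test(0.0, np.zeros(100), alpha=0.001)
        assert res.p == 1.0 and not res.keep

    def test_extreme_separation_kept(self):
        null = np.random.default_rng(0).normal(10.0, 0.5, 100)
        res = significance_test(1000.0, null, alpha=0.001)
        assert res.p < 0.001 and res.keep

    def test_zero_spread_nonzero_mean_kept(self):
        res = significance_test(5.0, np.full(100, 2.0), alpha=0.001)
        assert res.p == 0.0 and res.keep

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            significance_test(1.0, np.array([2.0]))

    def test_ensemble_statistic_is_calibrated(self):
        # the prediction-form alternative statistic should reject ~alpha
        # when the observation is an extra draw from the null
        rng = np.random.default_rng(12345)
        alpha = 0.05
        n_rep = 2000
        rej = sum(
            significance_test(
                rng.normal(3, 1.5), rng.normal(3, 1.5, 100), alpha, "ensemble"
            ).keep
            for _ in range(n_rep)
        )
        rate = rej / n_rep
        half = 2.576 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < half + 0.005


class TestControlChart:
    def test_identical_skewness_not_flagged(self):
        bc = {f"v{i}": float(i) for i in range(20)}
        chart = control_chart([bc, bc, bc], bc)
        assert chart.flagged == []

    def test_gross_outlier_flagged(self):
        # ten null networks share the reference's symmetric BC shape; an
        # eleventh with a one-hot (highly skewed) BC distribution must be
        # flagged: sigma = |delta|*sqrt(1/11) so |delta| > 3 sigma
        base = {f"v{i}": float(i) for i in range(50)}
        outlier = {f"v{i}": float(i == 0) for i in range(50)}
        nulls = [dict(base) for _ in range(10)] + [outlier]
        chart = control_chart(nulls, base)
        assert chart.flagged == [10]


class TestTune:
    def test_alpha_one_removes_only_zero_difference_nodes(self):
        g = nx_from_adj(random_adjacency(25, 0.2, 7))
        tuned, report = tune(g, alpha=1.0, n_random=20, seed=7, control=False)
        zero_diff = {
            row.node
            for row in report.table.itertuples()
            if row.p == 1.0
        }
        assert report.discarded() == zero_diff

    def test_tuned_network_is_subset(self):
        g = nx_from_adj(random_adjacency(30, 0.15, 1))
        tuned, _ = tune(g, alpha=0.01, n_random=20, seed=1, control=False)
        assert set(tuned.nodes) <= set(g.nodes)
        assert {frozenset(e) for e in tuned.edges} <= {
            frozenset(e) for e in g.edges
        }

    def test_deterministic_report(self):
        g = nx_from_adj(random_adjacency(25, 0.2, 9))
        _, r1 = tune(g, n_random=15, seed=5, control=False)
        _, r2 = tune(g, n_random=15, seed=5, control=False)
        assert r1.table.equals(r2.table)
        assert r1.null_seeds == r2.null_seeds

    def test_alpha_monotone_nesting(self):
        g = nx_from_adj(random_adjacency(30, 0.15, 11))
        discards = {}
        for alpha in (0.001, 0.01, 0.1):
            _, rep = tune(g, alpha=alpha, n_random=20, seed=11, control=False)
            discards[alpha] = rep.discarded()
        assert discards[0.001] >= discards[0.01] >= discards[0.1]

    def test_protected_nodes_survive(self):
        g = nx.star_graph([f"s{i}" for i in range(8)])
        protect = {"s3"}
        tuned, _ = tune(g, alpha=0.001, n_random=10, seed=0, control=False,
                        protect=protect)
        assert "s3" in tuned
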