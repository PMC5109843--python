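"""Threshold networks and induced-subgraph connectivity metrics vs brute force."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from sabre import ExpressionMatrix, GeneModule, ModuleSet, generate_null
from sabre.topology import (
    GeneNetwork,
    build_threshold_network,
    module_topology_metrics,
    stability_topology_correlation,
)


def matrix_with_correlations(rng, n_features=10, n_samples=200):
    x = generate_null(n_features, n_samples, seed=int(rng.integers(2**31)))
    return x


def brute_force_edges(x, k_sd):
    cor = np.corrcoef(x.values)
    pairs = list(combinations(range(x.n_features), 2))
    vals = np.array([abs(cor[i, j]) for i, j in pairs])
    thr = vals.mean() + k_sd * vals.std()
    return {
        frozenset((x.feature_ids[i], x.feature_ids[j]))
        for (i, j), v in zip(pairs, vals)
        if v >= thr
    }


class TestBuildThresholdNetwork:
    def test_single_strong_pair(self):
        # 3 features, one highly correlated pair: at k_sd=1 only it survives
        rng = np.random.default_rng(0)
        a = rng.standard_normal(300)
        b = 0.95 * a + 0.1 * rng.standard_normal(300)
        c = rng.standard_normal(300)
        x = ExpressionMatrix(("a", "b", "c"), tuple(f"s{i}" for i in range(300)), np.vstack([a, b, c]))
        net = build_threshold_network(x, k_sd=1.0)
        assert net.edges == {frozenset(("a", "b"))}

    def test_vacuous_threshold_gives_complete_graph(self, rng):
        x = matrix_with_correlations(rng, n_features=8)
        net = build_threshold_network(x, k_sd=-100.0)
        assert len(net.edges) == 8 * 7 // 2

    def test_edges_match_brute_force(self, rng):
        x = matrix_with_correlations(rng, n_features=50, n_samples=60)
        net = build_threshold_network(x, k_sd=1.0)
        assert net.edges == brute_force_edges(x, 1.0)

    def test_invariant_to_feature_order(self, rng):
        x = matrix_with_correlations(rng, n_features=12)
        perm = rng.permutation(x.n_features)
        xp = ExpressionMatrix(tuple(x.feature_ids[i] for i in perm), x.sample_ids, x.values[perm])
        assert build_threshold_network(x, 1.0).edges == build_threshold_network(xp, 1.0).edges

    def test_zero_variance_feature_excluded(self, rng):
        x = matrix_with_correlations(rng, n_features=5)
        values = np.vstack([x.values, np.ones(x.n_samples)])
        xz = ExpressionMatrix(x.feature_ids + ("flat",), x.sample_ids, values)
        net = build_threshold_network(xz, 1.0)
        assert "flat" not in net.nodes

    def test_self_loops_rejected(self):
        with pytest.raises(ValueError, match="self-loops"):
            GeneNetwork(("a",), frozenset({frozenset(("a",))}), 0.5)


def brute_force_metrics(g, members):
    """Independent enumeration of the three module metrics on a subgraph."""
    sub = g.subgraph(members)
    n = len(members)
    avg_deg = np.mean([d for _, d in sub.degree()]) if n else np.nan
    appearances = 0
    for s, t in combinations(members, 2):
        if not nx.has_path(sub, s, t):
            continue
        for path in nx.all_shortest_paths(sub, s, t):
            appearances += len(path) - 2
    triads = sum(
        1
        for trio in combinations(members, 3)
        if all(sub.has_edge(u, v) for u, v in combinations(trio, 2))
    )
    return avg_deg / n, appearances, triads / (n * (n - 1) * (n - 2) / 6) if n >= 3 else np.nan


class TestModuleTopologyMetrics:
    def _net_from_graph(self, g):
        return GeneNetwork(tuple(g.nodes), frozenset(frozenset(e) for e in g.edges), 0.0)

    def test_triangle_module(self):
        g = nx.complete_graph(["a", "b", "c"])
        ms = ModuleSet((GeneModule("K3", {"a", "b", "c"}),))
        table = module_topology_metrics(self._net_from_graph(g), ms).iloc[0]
        assert table["triad_density"] == 1.0
        assert table["avg_neighbors_norm"] == pytest.approx(2 / 3)
        assert table["shortest_path_appearances"] == 0.0

    def test_path_module_interior_node(self):
        g = nx.path_graph(["a", "b", "c"])
        ms = ModuleSet((GeneModule("P3", {"a", "b", "c"}),))
        row = module_topology_metrics(self._net_from_graph(g), ms).iloc[0]
        assert row["shortest_path_appearances"] == 1.0  # b inside a-c
        assert row["triad_density"] == 0.0

    def test_small_module_triads_missing(self):
        g = nx.path_graph(["a", "b"])
        ms = ModuleSet((GeneModule("P2", {"a", "b"}),))
        row = module_topology_metrics(self._net_from_graph(g), ms).iloc[0]
        assert np.isnan(row["triad_density"])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_random_subgraphs(self, trial):
        rng = np.random.default_rng(500 + trial)
        nodes = [f"n{i}" for i in range(25)]
        g = nx.gnp_random_graph(25, 0.25, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, dict(enumerate(nodes)))
        members = frozenset(rng.choice(nodes, size=10, replace=False))
        ms = ModuleSet((GeneModule("m", members),), frozenset(nodes) - members)
        row = module_topology_metrics(self._net_from_graph(g), ms).iloc[0]
        exp_deg, exp_paths, exp_triads = brute_force_metrics(g, sorted(members))
        assert row["avg_neighbors_norm"] == pytest.approx(exp_deg)
        assert row["shortest_path_appearances"] == exp_paths
        assert row["triad_density"] == pytest.approx(exp_triads)


class TestStabilityTopologyCorrelation:
    def _metrics(self, values):
        import pandas as pd

        return pd.DataFrame(
            {
                "module": [f"m{i}" for i in range(len(values))],
                "module_size": 10,
                "avg_neighbors_norm": values,
                "shortest_path_appearances": values,
                "triad_density": values,
            }
        )

    def test_concordant_ranks(self):
        metrics = self._metrics([0.1, 0.2, 0.3, 0.4])
        h = {f"m{i}": 0.2 * i for i in range(4)}
        out = stability_topology_correlation(metrics, h)
        assert all(rho == pytest.approx(1.0) for rho, _ in out.values())

    def test_reversed_ranks(self):
        metrics = self._metrics([0.4, 0.3, 0.2, 0.1])
        h = {f"m{i}": 0.2 * i for i in range(4)}
        out = stability_topology_correlation(metrics, h)
        assert all(rho == pytest.approx(-1.0) for rho, _ in out.values())

    def test_matches_rank_formula_on_hand_vectors(self):
        from scipy import stats

        vals = [0.3, 0.9, 0.1, 0.7, 0.5]
        hs = [0.2, 0.95, 0.3, 0.6, 0.4]
        metrics = self._metrics(vals)
        h = {f"m{i}": hs[i] for i in range(5)}
        rho, p = stability_topology_correlation(metrics, h)["triad_density"]
        # closed-form Spearman on ranks without ties: 1 - 6*sum(d^2)/(n(n^2-1))
        rx = stats.rankdata(vals)
        ry = stats.rankdata(hs)
        d2 = float(((rx - ry) ** 2).sum())
        assert rho == pytest.approx(1 - 6 * d2 / (5 * 24))

    def test_constant_metric_reported_missing(self):
        metrics = self._metrics([0.5, 0.5, 0.5, 0.5])
        h = {f"m{i}": 0.2 * i for i in range(4)}
        out = stability_topology_correlation(metrics, h)
        assert all(np.isnan(rho) for rho, _ in out.values())
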