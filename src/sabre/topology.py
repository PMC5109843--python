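"""Correlation-threshold networks and per-module connectivity metrics.

An undirected gene network is built by thresholding absolute pairwise
correlations: an edge joins two genes when their |correlation| is at least
``k_sd`` standard deviations above the mean over all gene pairs.  For each
module, three connectivity metrics are computed on the subgraph induced by
its members:

* mean degree divided by module size;
* the number of times a member gene sits strictly inside a shortest path
  between two other members (all shortest paths between a pair counted);
* triangle count divided by the number of possible triples.

Correlating these metrics with per-module H-indexes (Spearman) asks whether
stable modules are also the topologically tight ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, ModuleSet

__all__ = [
    "GeneNetwork",
    "build_threshold_network",
    "module_topology_metrics",
    "stability_topology_correlation",
    "METRIC_COLUMNS",
]

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("avg_neighbors_norm", "shortest_path_appearances", "triad_density")


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected, unweighted gene network from correlation thresholding."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    threshold: float

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("self-loops are not allowed")
            if not e <= known:
                raise ValueError(f"edge {set(e)} references unknown nodes")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


def build_threshold_network(x: ExpressionMatrix, k_sd: float = 2.0, signed_mean: bool = False) -> GeneNetwork:
    """Edge (i, j) iff |cor_ij| >= mean + k_sd * sd over all off-diagonal pairs.

    By default both the mean and the standard deviation are computed on the
    absolute correlations; ``signed_mean=True`` computes them on the signed
    values instead (the threshold still applies to |cor|).  Zero-variance
    features are excluded with a warning.
    """
    if x.n_features < 2:
        raise ValueError("need >= 2 features")
    sd = x.values.std(axis=1)
    keep = [f for f, s in zip(x.feature_ids, sd) if s > 0]
    if len(keep) < x.n_features:
        log.warning("excluding %d zero-variance feature(s) from the network", x.n_features - len(keep))
    xq = x.subset_features(keep)
    cor = np.corrcoef(xq.values)
    np.fill_diagonal(cor, np.nan)
    tri = cor[np.triu_indices(xq.n_features, k=1)]
    base = tri if signed_mean else np.abs(tri)
    threshold = float(base.mean() + k_sd * base.std())
    abs_cor = np.abs(cor)
    ii, jj = np.where(np.triu(abs_cor >= threshold, k=1))
    edges = frozenset(frozenset((keep[i], keep[j])) for i, j in zip(ii, jj))
    return GeneNetwork(nodes=tuple(keep), edges=edges, threshold=threshold)


def _interior_appearances(sub: nx.Graph) -> int:
    """Total appearances of member genes strictly inside shortest paths
    between pairs of other members; every shortest path of a pair counts."""
    total = 0
    nodes = list(sub.nodes)
    for s, t in combinations(nodes, 2):
        try:
            for path in nx.all_shortest_paths(sub, s, t):
                total += max(0, len(path) - 2)
        except nx.NetworkXNoPath:
            continue
    return total


def module_topology_metrics(net: GeneNetwork, ms: ModuleSet) -> pd.DataFrame:
    """Connectivity metrics per module, on the member-induced subgraph.

    Modules with fewer than 3 members get a missing triad density (no triple
    exists).  Disconnected member pairs contribute no shortest paths.
    """
    g = net.to_networkx()
    known = set(net.nodes)
    rows = []
    for m in ms.modules:
        members = [f for f in sorted(m.members) if f in known]
        sub = g.subgraph(members)
        n = len(members)
        if n == 0:
            rows.append({"module": m.name, "module_size": m.size,
                         "avg_neighbors_norm": np.nan,
                         "shortest_path_appearances": np.nan, "triad_density": np.nan})
            continue
        degrees = [d for _, d in sub.degree()]
        avg_norm = float(np.mean(degrees)) / m.size
        paths = _interior_appearances(sub)
        if n >= 3:
            triads = sum(nx.triangles(sub).values()) / 3
            triad_density = triads / (n * (n - 1) * (n - 2) / 6)
        else:
            triad_density = np.nan
        rows.append({"module": m.name, "module_size": m.size,
                     "avg_neighbors_norm": avg_norm,
                     "shortest_path_appearances": float(paths),
                     "triad_density": triad_density})
    return pd.DataFrame(rows)


def stability_topology_correlation(
    metrics: pd.DataFrame, h: Mapping[str, float]
) -> dict[str, tuple[float, float]]:
    """Spearman rho and two-sided p between each metric and the H-index.

    Constant metrics (rho undefined) are reported as (nan, nan).
    """
    merged = metrics.copy()
    merged["h_index"] = merged["module"].map(h)
    merged = merged.dropna(subset=["h_index"])
    out: dict[str, tuple[float, float]] = {}
    for col in METRIC_COLUMNS:
        sub = merged.dropna(subset=[col])
        if len(sub) < 3 or sub[col].nunique() == 1 or sub["h_index"].nunique() == 1:
            out[col] = (float("nan"), float("nan"))
            continue
        rho, p = stats.spearmanr(sub[col], sub["h_index"])
        out[col] = (float(rho), float(p))
    return out
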