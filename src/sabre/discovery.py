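"""Gene-module discovery algorithms behind a common, re-runnable interface.

Two algorithms are built in:

* ``wgcna_like`` — unsigned weighted co-expression clustering: Pearson
  correlation between gene rows, soft-thresholded to an adjacency
  ``a_ij = |cor|^beta``, converted to a topological-overlap dissimilarity,
  average-linkage clustered and cut statically at a fixed height.  Clusters
  below the minimum size join the unassigned remainder.
* ``kmeans_chaussabel`` — k-means over genes as points in sample space
  (Euclidean distance), multiple random initialisations, best
  within-cluster sum of squares retained; every gene is assigned.

Both are deterministic given their inputs and a seed, which is what allows
the bootstrap stability loop to re-run them on every re-sampled matrix.
Third-party algorithms (e.g. a PLS-based gene-gene interaction clustering)
plug in through :func:`register_algorithm`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core_io import ExpressionMatrix, GeneModule, ModuleSet

__all__ = [
    "DiscoveryConfig",
    "discover_wgcna_like",
    "discover_kmeans_chaussabel",
    "pick_soft_power",
    "choose_k_elbow",
    "register_algorithm",
    "get_algorithm",
    "discover",
    "topological_overlap",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Shared configuration for the discovery algorithms.

    cut_height: static dendrogram cut, on the normalised dissimilarity scale
        by default (see ``normalize_dissimilarity``).
    min_module_size: clusters below this size are moved to unassigned
        (hierarchical algorithms only).
    soft_power: soft-threshold exponent beta, or "auto" to pick the smallest
        power in 1..12 reaching scale-free fit R^2 >= 0.8.
    k: number of k-means clusters, or "elbow" for the variance-explained
        elbow criterion.
    dissimilarity: "tom" (1 - topological overlap, the weighted-network
        convention) or "adjacency" (1 - a_ij).
    normalize_dissimilarity: map pairwise dissimilarities to their empirical
        quantiles before clustering so the cut height is scale-free (a cut at
        h keeps average-linkage groups whose mutual dissimilarities sit in
        the smallest fraction h of all pairs).
    """

    algorithm: str = "wgcna_like"
    cut_height: float = 0.15
    min_module_size: int = 50
    soft_power: int | str = 6
    k: int | str = "elbow"
    n_starts: int = 10
    seed: int = 0
    dissimilarity: str = "tom"
    normalize_dissimilarity: bool = True
    elbow_threshold: float = 0.01
    elbow_k_range: tuple[int, ...] = tuple(range(2, 11))

    def __post_init__(self) -> None:
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.dissimilarity not in ("tom", "adjacency"):
            raise ValueError("dissimilarity must be 'tom' or 'adjacency'")

    def with_seed(self, seed: int) -> "DiscoveryConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# weighted co-expression network pieces
# ---------------------------------------------------------------------------

def _row_correlation(values: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cor = np.corrcoef(values)
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def _drop_zero_variance(x: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    sd = x.values.std(axis=1)
    dead = [f for f, s in zip(x.feature_ids, sd) if s == 0.0]
    if dead:
        log.warning("excluding %d zero-variance feature(s) from network construction", len(dead))
        keep = [f for f in x.feature_ids if f not in set(dead)]
        x = x.subset_features(keep)
    return x, dead


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of a weighted adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with a
    unit diagonal.  High overlap means two genes share most of their network
    neighbourhood, not merely a strong direct edge.
    """
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) ~ log10(mean connectivity) over equal-width bins.

    The conventional goodness-of-fit of a degree distribution to a power law;
    used to pick the soft-threshold exponent.
    """
    k = np.asarray(connectivity, dtype=float)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all values equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = (counts > 0) & (centers > 0)
    if mask.sum() < 3:
        return 0.0
    logk = np.log10(centers[mask])
    logp = np.log10(counts[mask] / k.size)
    slope, intercept = np.polyfit(logk, logp, 1)
    resid = logp - (slope * logk + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def pick_soft_power(
    x: ExpressionMatrix,
    candidate_powers: list[int] | tuple[int, ...] = tuple(range(1, 13)),
    target_r2: float = 0.8,
) -> int:
    """Smallest soft-threshold power whose scale-free fit reaches target_r2.

    Falls back to the best-fitting candidate (with a warning) when no power
    reaches the target.
    """
    candidates = list(candidate_powers)
    if not candidates:
        raise ValueError("candidate_powers must be non-empty")
    if sorted(candidates) != candidates:
        raise ValueError("candidate_powers must be ascending")
    xq, _ = _drop_zero_variance(x)
    cor = np.abs(_row_correlation(xq.values))
    np.fill_diagonal(cor, 0.0)
    fits: list[float] = []
    for beta in candidates:
        k = (cor**beta).sum(axis=1)
        r2 = scale_free_fit(k)
        fits.append(r2)
        if r2 >= target_r2:
            return beta
    best = candidates[int(np.argmax(fits))]
    log.warning(
        "no candidate power reached scale-free R^2 %.2f (best %.3f at power %d)",
        target_r2, max(fits), best,
    )
    return best


def _quantile_transform(condensed: np.ndarray) -> np.ndarray:
    """Map pairwise dissimilarities to their empirical quantiles in (0, 1].

    Makes the dendrogram cut height scale-free: under average linkage a cut
    at height h groups genes whose average mutual dissimilarity lies within
    the smallest fraction h of all gene pairs, whatever the raw scale of the
    dissimilarity (1-TOM, 1-adjacency, ...).
    """
    from scipy.stats import rankdata

    return rankdata(condensed) / condensed.size


def discover_wgcna_like(x: ExpressionMatrix, cfg: DiscoveryConfig) -> ModuleSet:
    """Unsigned weighted co-expression module discovery.

    Pipeline: |Pearson cor|^beta adjacency -> dissimilarity (1 - TOM by
    default) -> average-linkage dendrogram -> static cut at ``cfg.cut_height``
    -> clusters below ``cfg.min_module_size`` dropped to unassigned.  Modules
    are named W01, W02, ... by decreasing size.
    """
    if x.n_samples < 4:
        raise ValueError("need >= 4 samples for meaningful correlations")
    xq, dead = _drop_zero_variance(x)
    if xq.n_features < 2:
        raise ValueError("need >= 2 variable features")
    beta = pick_soft_power(xq) if cfg.soft_power == "auto" else int(cfg.soft_power)
    adjacency = np.abs(_row_correlation(xq.values)) ** beta
    if cfg.dissimilarity == "tom":
        dissim = 1.0 - topological_overlap(adjacency)
    else:
        dissim = 1.0 - adjacency
        np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    condensed = squareform(dissim, checks=False)
    if cfg.normalize_dissimilarity:
        condensed = _quantile_transform(condensed)
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=cfg.cut_height, criterion="distance")
    modules: list[frozenset[str]] = []
    unassigned: set[str] = set(dead)
    for lab in np.unique(labels):
        members = frozenset(f for f, l in zip(xq.feature_ids, labels) if l == lab)
        if len(members) >= cfg.min_module_size:
            modules.append(members)
        else:
            unassigned |= members
    modules.sort(key=lambda m: (-len(m), min(m)))
    named = tuple(GeneModule(f"W{i:02d}", m) for i, m in enumerate(modules, start=1))
    return ModuleSet(
        modules=named,
        unassigned=frozenset(unassigned),
        provenance={
            "algorithm": "wgcna_like",
            "soft_power": beta,
            "cut_height": cfg.cut_height,
            "min_module_size": cfg.min_module_size,
            "dissimilarity": cfg.dissimilarity,
            "normalize_dissimilarity": cfg.normalize_dissimilarity,
            "sample_ids": list(x.sample_ids),
            "seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# k-means (Chaussabel-style)
# ---------------------------------------------------------------------------

def _kmeans_best_of(
    values: np.ndarray, k: int, n_starts: int, seed: int
) -> tuple[np.ndarray, float, list[float]]:
    """Run n_starts single-init k-means fits; keep the minimal-WSS solution.

    Explicit starts (rather than one multi-init fit) so the retained WSS can
    be audited against every start's WSS.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_starts) % (2**31)
    best_labels, best_wss = None, np.inf
    all_wss: list[float] = []
    for s in seeds:
        km = KMeans(n_clusters=k, n_init=1, random_state=int(s)).fit(values)
        all_wss.append(float(km.inertia_))
        if km.inertia_ < best_wss:
            best_wss, best_labels = float(km.inertia_), km.labels_
    assert best_labels is not None
    return best_labels, best_wss, all_wss


def discover_kmeans_chaussabel(x: ExpressionMatrix, cfg: DiscoveryConfig) -> ModuleSet:
    """K-means module discovery over genes in sample space.

    Genes are points in R^n_samples; Euclidean k-means with ``cfg.n_starts``
    random initialisations retains the partition with minimal within-cluster
    sum of squares.  Every gene is assigned (no unassigned remainder); k is
    fixed up front or chosen by the elbow criterion.  Modules are named
    M01..Mk in cluster-label order.
    """
    k = cfg.k
    if k == "elbow":
        k_range = [kk for kk in cfg.elbow_k_range if kk <= x.n_features]
        k = choose_k_elbow(x, k_range, seed=cfg.seed, threshold=cfg.elbow_threshold, n_starts=cfg.n_starts)
    k = int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.n_features:
        raise ValueError(f"k={k} exceeds feature count {x.n_features}")
    labels, wss, all_wss = _kmeans_best_of(x.values, k, cfg.n_starts, cfg.seed)
    modules = []
    for lab in range(k):
        members = frozenset(f for f, l in zip(x.feature_ids, labels) if l == lab)
        if members:
            modules.append(members)
    named = tuple(GeneModule(f"M{i:02d}", m) for i, m in enumerate(modules, start=1))
    return ModuleSet(
        modules=named,
        unassigned=frozenset(),
        provenance={
            "algorithm": "kmeans_chaussabel",
            "k": k,
            "n_starts": cfg.n_starts,
            "wss": wss,
            "all_start_wss": all_wss,
            "sample_ids": list(x.sample_ids),
            "seed": cfg.seed,
        },
    )


def explained_variance_path(
    x: ExpressionMatrix, k_range: list[int], seed: int, n_starts: int = 10
) -> list[float]:
    """Proportion of variance explained (between-cluster SS / total SS) per k."""
    values = x.values
    tss = float(((values - values.mean(axis=0)) ** 2).sum())
    if tss == 0.0:
        raise ValueError("zero total variance")
    pves = []
    for k in k_range:
        if k <= 1:
            pves.append(0.0)
            continue
        _, wss, _ = _kmeans_best_of(values, k, n_starts, seed)
        pves.append(1.0 - wss / tss)
    return pves


def choose_k_elbow(
    x: ExpressionMatrix,
    k_range: list[int] | tuple[int, ...],
    seed: int = 0,
    threshold: float = 0.01,
    n_starts: int = 10,
) -> int:
    """Elbow criterion: smallest k whose marginal variance-explained gain
    over k-1 drops below ``threshold``; max(k_range) with a warning if the
    gains never fall that low."""
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if sorted(ks) != ks:
        raise ValueError("k_range must be ascending")
    path = explained_variance_path(x, [ks[0] - 1] + ks, seed=seed, n_starts=n_starts)
    for i, k in enumerate(ks):
        gain = path[i + 1] - path[i]
        if gain < threshold:
            return k
    log.warning("all elbow gains above %.3g; returning max(k_range)=%d", threshold, ks[-1])
    return ks[-1]


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

DiscoveryFn = Callable[[ExpressionMatrix, DiscoveryConfig], ModuleSet]

_REGISTRY: dict[str, DiscoveryFn] = {
    "wgcna_like": discover_wgcna_like,
    "kmeans_chaussabel": discover_kmeans_chaussabel,
}


def register_algorithm(name: str, fn: DiscoveryFn) -> None:
    """Make a third-party discovery algorithm available by name."""
    if name in _REGISTRY:
        raise ValueError(f"algorithm {name!r} already registered")
    _REGISTRY[name] = fn


def get_algorithm(name: str) -> DiscoveryFn:
    if name not in _REGISTRY:
        raise KeyError(f"unknown algorithm {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


def discover(x: ExpressionMatrix, cfg: DiscoveryConfig) -> ModuleSet:
    """Dispatch to the configured algorithm."""
    return get_algorithm(cfg.algorithm)(x, cfg)
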