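"""Bootstrap stability assessment of gene modules (SABRE) and the H-index.

The procedure: discover a *reference* module set from the full expression
matrix; draw B bootstrap re-samplings of the samples (columns, with
replacement); re-run the same discovery algorithm on every re-sampled
matrix; score each reference module against each replicate module set by its
*best match* similarity; and summarise each module's B scores with the
Hirsch-style H-index

    H(q) = max { h : (1/B) * #{ j : R_j >= h } >= h },

the largest h such that similarity >= h was observed in at least a fraction
h of replicates.  H = 0.8 reads: similarity of 0.8 or better in at least
80% of bootstrap runs — a minimum-quality guarantee that neither the mean
nor the area under the sorted-score curve provides.

The public surface follows the model/results convention: build a
:class:`SABRE` object from a matrix and a discovery configuration, call
``fit`` to obtain a :class:`SabreResult`.  ``run_sabre`` is the functional
equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneModule, ModuleSet, StabilityDistribution
from .discovery import DiscoveryConfig, discover, get_algorithm
from .similarity import best_match, resolve_measure

__all__ = ["bootstrap_indices", "h_index_of", "SABRE", "SabreResult", "run_sabre", "random_module_baseline"]


def bootstrap_indices(n: int, B: int, seed: int) -> np.ndarray:
    """B rows of n sample indices drawn uniformly with replacement from 0..n-1."""
    if n < 1 or B < 1:
        raise ValueError("n and B must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(B, n))


def h_index_of(scores: Sequence[float] | np.ndarray) -> float:
    """H-index of a vector of similarity scores in [0, 1].

    Sort descending as s(1) >= ... >= s(N); the H-index is
    ``max_j min(s(j), j/N)``, which equals the supremum over h of the
    condition "a fraction >= h of scores is >= h".
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("scores must be a non-empty 1-D vector")
    if np.any((s < 0) | (s > 1)) or not np.all(np.isfinite(s)):
        raise ValueError("scores must lie in [0, 1]")
    s = np.sort(s)[::-1]
    ranks = np.arange(1, s.size + 1) / s.size
    return float(np.max(np.minimum(s, ranks)))


@dataclass(frozen=True)
class SabreResult:
    """Fitted bootstrap-stability result.

    Attributes
    ----------
    reference : the module set discovered from the full data.
    distributions : per reference module, its B best-match scores.
    h_index : per-module H-index, each recomputable from its distribution.
    replicate_module_sets : the B re-discovered module sets (None entries mark
        failed replicates, which scored 0 for every module).
    """

    reference: ModuleSet
    distributions: Mapping[str, StabilityDistribution]
    h_index: Mapping[str, float]
    n_boot: int
    seed: int
    measure: str
    replicate_module_sets: tuple[ModuleSet | None, ...] = ()
    n_failed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "distributions", dict(self.distributions))
        object.__setattr__(self, "h_index", dict(self.h_index))
        for name, dist in self.distributions.items():
            if dist.n_bootstrap != self.n_boot:
                raise ValueError(f"distribution for {name!r} has length {dist.n_bootstrap}, expected {self.n_boot}")

    def summary(self) -> pd.DataFrame:
        """Per-module stability table, most stable first."""
        rows = []
        for m in self.reference.modules:
            scores = self.distributions[m.name].scores
            rows.append(
                {
                    "module": m.name,
                    "size": m.size,
                    "h_index": self.h_index[m.name],
                    "mean_score": float(scores.mean()),
                    "median_score": float(np.median(scores)),
                    "min_score": float(scores.min()),
                }
            )
        table = pd.DataFrame(rows).sort_values("h_index", ascending=False, kind="stable")
        return table.reset_index(drop=True)

    def scores_frame(self) -> pd.DataFrame:
        """Long-format {module, replicate, score} table."""
        rows = [
            {"module": name, "replicate": j, "score": float(s)}
            for name, dist in self.distributions.items()
            for j, s in enumerate(dist.scores)
        ]
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        table = self.summary()
        head = (
            f"SABRE stability ({self.n_boot} bootstraps, measure={self.measure}, "
            f"seed={self.seed}, failed replicates={self.n_failed})\n"
        )
        return head + table.to_string(index=False, float_format=lambda v: f"{v:.3f}")

    def plot_stability(self, ax=None):
        """Box plots of per-module score distributions, H-index overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, 0.5 * len(self.reference)), 4))
        order = self.summary()["module"].tolist()
        data = [self.distributions[m].scores for m in order]
        ax.boxplot(data, tick_labels=order)
        ax.plot(range(1, len(order) + 1), [self.h_index[m] for m in order], "ro", label="H-index")
        ax.set_ylabel("best-match similarity")
        ax.set_xlabel("module")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        ax.tick_params(axis="x", rotation=90)
        return ax

    def random_baseline(
        self,
        sizes: Sequence[int] = tuple(range(50, 401, 50)),
        reps: int = 100,
        seed: int = 0,
        measure: str | None = None,
    ) -> dict[int, np.ndarray]:
        """Random-module baseline scored against this fit's replicate sets."""
        return random_module_baseline(
            feature_universe=sorted(self.reference.universe),
            sizes=sizes,
            reps=reps,
            bootstrap_sets=[q for q in self.replicate_module_sets if q is not None],
            seed=seed,
            measure=measure or self.measure,
        )


class SABRE(object):
    """Stability Assessment via Bootstrap RE-sampling of a module discovery.

    Parameters
    ----------
    x : ExpressionMatrix
        Features x samples expression data.
    config : DiscoveryConfig, optional
        Discovery algorithm and its parameters; defaults to the weighted
        co-expression algorithm at its defaults.

    Examples
    --------
    >>> from sabre import SABRE, DiscoveryConfig
    >>> from sabre.synthetic import PlantedDesign, generate_planted
    >>> x, truth = generate_planted(PlantedDesign(seed=1))
    >>> res = SABRE(x, DiscoveryConfig()).fit(n_boot=50, seed=1)
    >>> res.summary()  # doctest: +SKIP
    """

    def __init__(self, x: ExpressionMatrix, config: DiscoveryConfig | None = None):
        self.x = x
        self.config = config or DiscoveryConfig()
        get_algorithm(self.config.algorithm)  # fail fast on unknown algorithm

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: DiscoveryConfig | None = None) -> "SABRE":
        """Build from a features x samples DataFrame (index = feature ids)."""
        return cls(ExpressionMatrix.from_frame(frame), config)

    def discover_reference(self) -> ModuleSet:
        return discover(self.x, self.config)

    def fit(
        self,
        n_boot: int = 1000,
        measure: str = "min_overlap",
        seed: int = 0,
        indices: np.ndarray | None = None,
        max_failure_fraction: float = 0.5,
    ) -> SabreResult:
        """Run the bootstrap stability loop.

        Parameters
        ----------
        n_boot : number of bootstrap replicates B.
        measure : "accuracy", "jaccard" or "min_overlap" (default; exact
            subsets count as perfect matches).
        seed : master seed; per-replicate discovery seeds are spawned from it
            so serial and parallel execution agree.
        indices : optional (B, n_samples) integer array overriding the
            bootstrap draw — e.g. identity rows to force self-comparison.
        max_failure_fraction : abort if more than this fraction of replicates
            fails discovery; failed replicates score 0 for every module.
        """
        resolve_measure(measure)
        reference = self.discover_reference()
        if len(reference) == 0:
            raise RuntimeError("reference discovery produced zero modules")
        if indices is None:
            indices = bootstrap_indices(self.x.n_samples, n_boot, seed)
        else:
            indices = np.asarray(indices)
            if indices.shape != (n_boot, self.x.n_samples):
                raise ValueError("indices must have shape (n_boot, n_samples)")
        rep_seeds = np.random.SeedSequence(seed).generate_state(n_boot) % (2**31)
        scores = {m.name: np.zeros(n_boot) for m in reference.modules}
        replicate_sets: list[ModuleSet | None] = []
        n_failed = 0
        for j in range(n_boot):
            xb = self.x.subset_samples(indices[j])
            try:
                qb = discover(xb, self.config.with_seed(int(rep_seeds[j])))
                if len(qb) == 0:
                    raise RuntimeError("zero modules on replicate")
            except Exception:
                n_failed += 1
                replicate_sets.append(None)
                continue  # scores stay 0 for this replicate
            replicate_sets.append(qb)
            for m in reference.modules:
                scores[m.name][j], _ = best_match(m, qb, measure)
        if n_failed > max_failure_fraction * n_boot:
            raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed discovery")
        distributions = {name: StabilityDistribution(name, v) for name, v in scores.items()}
        h = {name: h_index_of(v) for name, v in scores.items()}
        return SabreResult(
            reference=reference,
            distributions=distributions,
            h_index=h,
            n_boot=n_boot,
            seed=seed,
            measure=measure if isinstance(measure, str) else getattr(measure, "__name__", "custom"),
            replicate_module_sets=tuple(replicate_sets),
            n_failed=n_failed,
        )


def run_sabre(
    x: ExpressionMatrix,
    cfg: DiscoveryConfig | None = None,
    B: int = 1000,
    measure: str = "min_overlap",
    seed: int = 0,
    indices: np.ndarray | None = None,
) -> SabreResult:
    """Functional wrapper around ``SABRE(x, cfg).fit(...)``."""
    return SABRE(x, cfg).fit(n_boot=B, measure=measure, seed=seed, indices=indices)


def random_module_baseline(
    feature_universe: Sequence[str],
    sizes: Sequence[int] = tuple(range(50, 401, 50)),
    reps: int = 100,
    bootstrap_sets: Sequence[ModuleSet] = (),
    seed: int = 0,
    measure: str = "min_overlap",
) -> dict[int, np.ndarray]:
    """Stability of modules assembled by chance.

    For each requested size, draw ``reps`` random modules (sampling features
    without replacement from the universe), score each by best match against
    every bootstrap module set, and summarise with the H-index.  The result
    maps size -> vector of ``reps`` H-indexes — the background a real
    module's stability should clear.
    """
    universe = list(feature_universe)
    if not bootstrap_sets:
        raise ValueError("bootstrap_sets must be non-empty")
    for size in sizes:
        if size > len(universe):
            raise ValueError(f"module size {size} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for size in sizes:
        hs = np.empty(reps)
        for r in range(reps):
            module = GeneModule(f"R{size}_{r}", frozenset(rng.choice(universe, size=size, replace=False)))
            s = np.array([best_match(module, q, measure)[0] for q in bootstrap_sets])
            hs[r] = h_index_of(s)
        out[int(size)] = hs
    return out
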