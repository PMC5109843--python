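"""Gene-set over-representation and the annotatability of modules.

A module's overlap with each gene set of a collection is scored with the
upper-tail hypergeometric test: drawing ``module_size`` genes from a
universe of ``universe_size`` genes of which ``set_size`` belong to the set,
p = P(X >= overlap).  A module's *annotatability* in a collection is the sum
of -log10 p over all its sets — a proxy for how readily the module maps onto
known biology.  Correlating annotatability with the H-index asks whether
stable modules are also the interpretable ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection, ModuleSet

__all__ = [
    "EnrichmentRow",
    "hypergeom_enrich",
    "enrichment_table",
    "annotatability_score",
    "annotatability_scores",
    "stability_annotatability_correlation",
]

#: Smallest p-value reported after floating-point underflow of the tail sum.
P_FLOOR = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class EnrichmentRow:
    module: str
    gene_set: str
    overlap: int
    module_size: int
    set_size_in_universe: int
    universe_size: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.module_size, self.set_size_in_universe):
            raise ValueError("overlap exceeds module or set size")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")


def hypergeom_enrich(
    ms: ModuleSet,
    coll: GeneSetCollection,
    universe: set[str] | frozenset[str] | None = None,
    restrict_sets: bool = True,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation of each module in each set.

    The universe defaults to the module set's own feature universe (the
    measured features).  Gene sets are intersected with the universe before
    testing (``restrict_sets=False`` keeps their full size as the success
    count, clipped to the universe).
    """
    universe = frozenset(universe) if universe is not None else ms.universe
    if not universe:
        raise ValueError("universe is empty")
    rows: list[EnrichmentRow] = []
    M = len(universe)
    for m in ms.modules:
        stray = m.members - universe
        if stray:
            raise ValueError(f"module {m.name!r} has members outside the universe: {sorted(stray)[:5]}")
        for set_name, genes in coll.sets.items():
            in_universe = genes & universe if restrict_sets else genes
            n_success = min(len(in_universe), M)
            overlap = len(m.members & in_universe)
            # P(X >= overlap); sf(k-1) is the exact upper tail
            p = float(stats.hypergeom.sf(overlap - 1, M, n_success, m.size))
            p = min(max(p, P_FLOOR), 1.0)
            rows.append(
                EnrichmentRow(
                    module=m.name,
                    gene_set=set_name,
                    overlap=overlap,
                    module_size=m.size,
                    set_size_in_universe=n_success,
                    universe_size=M,
                    p_value=p,
                )
            )
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Rows as a DataFrame with a BH-adjusted column (convenience only; the
    annotatability score always uses the raw p-values)."""
    table = pd.DataFrame([r.__dict__ for r in rows])
    if not table.empty:
        table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def annotatability_score(rows: Sequence[EnrichmentRow], module: str) -> float:
    """Sum of -log10 p over the collection's sets for one module."""
    ps = [r.p_value for r in rows if r.module == module]
    if not ps:
        raise ValueError(f"no enrichment rows for module {module!r}")
    return float(np.sum(-np.log10(ps)))


def annotatability_scores(rows: Sequence[EnrichmentRow]) -> dict[str, float]:
    modules = sorted({r.module for r in rows})
    return {m: annotatability_score(rows, m) for m in modules}


def stability_annotatability_correlation(
    scores: Mapping[str, float], h: Mapping[str, float]
) -> tuple[float, float]:
    """Spearman rho and two-sided p between annotatability and H-index."""
    common = sorted(set(scores) & set(h))
    if len(common) < 3:
        raise ValueError("need >= 3 modules with both scores")
    s = np.array([scores[m] for m in common])
    hh = np.array([h[m] for m in common])
    if np.unique(s).size == 1 or np.unique(hh).size == 1:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(s, hh)
    return float(rho), float(p)
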