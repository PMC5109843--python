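"""Set-similarity measures for comparing gene modules.

Three measures, all on [0, 1]:

* ``accuracy(q, q')``: |q ∩ q'| / |q| — the fraction of the reference module
  recovered; asymmetric in its arguments.
* ``jaccard(q, q')``: |q ∩ q'| / |q ∪ q'| — the classic symmetric overlap.
* ``min_overlap_similarity(q, q')``: |q ∩ q'| / min(|q|, |q'|) — the
  Simpson-index analogue.  A test module that is an exact subset of the
  reference (or vice versa) scores 1: from a stability standpoint a
  re-discovered core is a perfect match, so this is the default measure for
  bootstrap scoring.

``best_match`` scores a reference module against every module of a comparator
set and returns the maximum.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable

from .core_io import GeneModule, ModuleSet

__all__ = ["accuracy", "jaccard", "min_overlap_similarity", "best_match", "MEASURES", "cross_tabulate"]

log = logging.getLogger(__name__)

SetLike = GeneModule | frozenset | set


def _members(q: SetLike) -> frozenset:
    return q.members if isinstance(q, GeneModule) else frozenset(q)


def accuracy(q: SetLike, q2: SetLike) -> float:
    """Fraction of the reference module q recovered in q2. Not symmetric."""
    a, b = _members(q), _members(q2)
    if not a:
        raise ValueError("reference module is empty")
    return len(a & b) / len(a)


def jaccard(q: SetLike, q2: SetLike) -> float:
    """Intersection over union."""
    a, b = _members(q), _members(q2)
    union = a | b
    if not union:
        raise ValueError("both modules are empty")
    return len(a & b) / len(union)


def min_overlap_similarity(q: SetLike, q2: SetLike) -> float:
    """Intersection over the smaller module's size; exact subsets score 1."""
    a, b = _members(q), _members(q2)
    if not a or not b:
        raise ValueError("modules must be non-empty")
    return len(a & b) / min(len(a), len(b))


MEASURES: dict[str, Callable[[SetLike, SetLike], float]] = {
    "accuracy": accuracy,
    "jaccard": jaccard,
    "min_overlap": min_overlap_similarity,
}


def resolve_measure(measure: str | Callable[[SetLike, SetLike], float]) -> Callable[[SetLike, SetLike], float]:
    if callable(measure):
        return measure
    key = measure.replace("-", "_")
    if key not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    return MEASURES[key]


def best_match(
    q: SetLike,
    Q: ModuleSet | Iterable[GeneModule],
    measure: str | Callable[[SetLike, SetLike], float] = "min_overlap",
) -> tuple[float, str]:
    """Maximum similarity of q over the modules of Q, with the argmax name.

    Ties break to the first-encountered module in Q's stored order; unassigned
    features of Q are never a candidate.
    """
    fn = resolve_measure(measure)
    modules = list(Q.modules) if isinstance(Q, ModuleSet) else list(Q)
    if not modules:
        raise ValueError("comparator module set is empty")
    best_score, best_name = -1.0, ""
    tied = False
    for m in modules:
        s = fn(q, m)
        if s > best_score:
            best_score, best_name, tied = s, m.name, False
        elif s == best_score:
            tied = True
    if tied:
        log.debug("best_match tie at score %.4f; keeping first-encountered %r", best_score, best_name)
    return best_score, best_name


def cross_tabulate(
    reference: ModuleSet,
    comparator: ModuleSet,
    measure: str | Callable[[SetLike, SetLike], float] = "min_overlap",
):
    """All pairwise scores between two module sets as a DataFrame (rows = reference)."""
    import pandas as pd

    fn = resolve_measure(measure)
    data = {
        ref.name: {m.name: fn(ref, m) for m in comparator.modules}
        for ref in reference.modules
    }
    table = pd.DataFrame.from_dict(data, orient="index")
    table.index.name = "reference_module"
    return table
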