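"""Sample-size / module-size subsampling study.

How many samples does a stable module need?  The design: draw n expression
profiles without replacement, discover a reference module set on that
subsample, run the bootstrap stability loop within it, and record every
module's H-index and size.  Repeating over several n values and several
outer draws traces stability as a function of cohort size; comparing
small-module vs large-module H-indexes (1st vs 4th size quartile) with a
rank-sum test asks whether small modules are intrinsically less stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix
from .discovery import DiscoveryConfig
from .stability import SABRE

__all__ = ["SubsampleDesign", "run_subsample_study", "size_stability_test"]


@dataclass(frozen=True)
class SubsampleDesign:
    """Subsampling study layout.

    n_values: subsample sizes (drawn without replacement from the columns).
    outer_reps: independent subsample draws per n, capturing the effect the
        particular selection has on the reference module set.
    inner_bootstraps: bootstrap replicates of the stability loop within each
        subsample.
    """

    n_values: tuple[int, ...] = (10, 20, 40, 80, 120, 160)
    outer_reps: int = 10
    inner_bootstraps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_values", tuple(int(n) for n in self.n_values))
        if self.outer_reps < 1 or self.inner_bootstraps < 1:
            raise ValueError("outer_reps and inner_bootstraps must be >= 1")
        if any(n < 1 for n in self.n_values):
            raise ValueError("n_values must be positive")


def run_subsample_study(
    x: ExpressionMatrix,
    cfg: DiscoveryConfig,
    design: SubsampleDesign,
    measure: str = "min_overlap",
) -> pd.DataFrame:
    """Long-format table of {n, outer_rep, module, module_size, h_index, failed}.

    Subsamples for which discovery is undefined (too few samples for
    correlations, or zero modules found) appear as flagged rows rather than
    being silently dropped.
    """
    if max(design.n_values) > x.n_samples:
        raise ValueError("n_values exceed available samples")
    root = np.random.SeedSequence(design.seed)
    rows: list[dict] = []
    for n in design.n_values:
        for rep in range(design.outer_reps):
            child = np.random.SeedSequence((design.seed, n, rep))
            rng = np.random.default_rng(child)
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            if n == x.n_samples:
                cols = np.arange(x.n_samples)
            else:
                cols = rng.choice(x.n_samples, size=n, replace=False)
            xs = x.subset_samples(cols)
            try:
                res = SABRE(xs, cfg).fit(n_boot=design.inner_bootstraps, measure=measure, seed=sub_seed)
            except (ValueError, RuntimeError) as exc:
                rows.append(
                    {"n": n, "outer_rep": rep, "module": None, "module_size": np.nan,
                     "h_index": np.nan, "failed": str(exc)}
                )
                continue
            for m in res.reference.modules:
                rows.append(
                    {"n": n, "outer_rep": rep, "module": m.name, "module_size": m.size,
                     "h_index": res.h_index[m.name], "failed": ""}
                )
    _ = root  # design.seed enters through the per-cell SeedSequence keys
    return pd.DataFrame(rows)


def size_stability_test(rows: pd.DataFrame, n: int) -> float:
    """Two-sided Wilcoxon rank-sum p comparing H-indexes of small (1st size
    quartile) vs large (4th size quartile) modules at sample size n.

    Quartile cut points come from the module sizes observed at that n.  The
    exact null distribution is used when the combined group size is <= 20,
    the continuity-corrected normal approximation otherwise.
    """
    at_n = rows[(rows["n"] == n) & (rows["failed"] == "")]
    if at_n.empty:
        raise ValueError(f"no successful runs at n={n}")
    sizes = at_n["module_size"].to_numpy(dtype=float)
    q1, q3 = np.quantile(sizes, [0.25, 0.75])
    small = at_n.loc[sizes <= q1, "h_index"].to_numpy()
    large = at_n.loc[sizes >= q3, "h_index"].to_numpy()
    if small.size < 2 or large.size < 2:
        raise ValueError("need >= 2 modules in each size-quartile group")
    combined = np.concatenate([small, large])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(small, large, alternative="two-sided", method=method)
    return float(res.pvalue)
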