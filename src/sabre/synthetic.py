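"""Synthetic expression matrices with planted co-expression modules.

Each planted module is driven by a single standard-normal latent factor
shared across its member genes:

    g = sqrt(w) * factor + sqrt(1 - w) * eps,   eps ~ N(0, noise_sd^2) i.i.d.

With ``noise_sd = 1`` the expected gene-gene correlation within a module is
exactly ``w`` and cross-module / background correlations are 0 in
expectation, so ground-truth membership is known and recovery can be scored
with the set-similarity measures.  Background genes are pure noise.

This emulates the coarse structure of a filtered microarray matrix — blocks
of coordinately expressed transcripts on an unstructured background — and
deliberately omits probe effects, batch structure and heavy-tailed noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionMatrix, GeneModule, ModuleSet

__all__ = ["PlantedDesign", "generate_planted", "generate_null"]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-module generator.

    n_samples: columns of the matrix (subjects).
    module_sizes: genes per planted module, one entry per module.
    within_cor: expected pairwise correlation within a module, in (0, 1).
    n_background: unstructured noise genes appended after the modules.
    noise_sd: standard deviation of the idiosyncratic term; values other
        than 1 shift the realised within-module correlation away from
        ``within_cor`` (w / (w + (1-w)·noise_sd²)).
    loading_sd: spread of per-gene factor loadings around sqrt(within_cor);
        0 (default) gives equal loadings, > 0 makes recovery harder.
    """

    n_samples: int = 100
    module_sizes: tuple[int, ...] = (60, 60, 60)
    within_cor: float = 0.8
    n_background: int = 180
    noise_sd: float = 1.0
    loading_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(int(s) for s in self.module_sizes))
        if not 0 < self.within_cor < 1:
            raise ValueError("within_cor must be in (0, 1)")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if self.n_samples < 1 or self.n_background < 0:
            raise ValueError("invalid dimensions")


def generate_planted(design: PlantedDesign) -> tuple[ExpressionMatrix, ModuleSet]:
    """Generate a planted-module matrix and its ground-truth module set.

    Returns (matrix, truth) where ``truth`` has one module per entry of
    ``design.module_sizes`` (named P01, P02, ...) and the background genes as
    the unassigned remainder.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    w = design.within_cor
    blocks: list[np.ndarray] = []
    modules: list[GeneModule] = []
    feature_ids: list[str] = []
    for k, size in enumerate(design.module_sizes, start=1):
        factor = rng.standard_normal(n)
        loadings = np.sqrt(w) + design.loading_sd * rng.standard_normal(size)
        eps = rng.standard_normal((size, n)) * design.noise_sd
        block = loadings[:, None] * factor[None, :] + np.sqrt(1.0 - w) * eps
        ids = [f"G{k:02d}_{i:04d}" for i in range(size)]
        feature_ids.extend(ids)
        blocks.append(block)
        modules.append(GeneModule(f"P{k:02d}", frozenset(ids)))
    bg_ids = [f"BG_{i:04d}" for i in range(design.n_background)]
    if design.n_background:
        blocks.append(rng.standard_normal((design.n_background, n)) * design.noise_sd)
        feature_ids.extend(bg_ids)
    values = np.vstack(blocks) if blocks else np.empty((0, n))
    sample_ids = tuple(f"S{j:04d}" for j in range(n))
    x = ExpressionMatrix(tuple(feature_ids), sample_ids, values)
    truth = ModuleSet(
        modules=tuple(modules),
        unassigned=frozenset(bg_ids),
        provenance={"generator": "planted", **_design_dict(design)},
    )
    return x, truth


def generate_null(n_features: int, n_samples: int, seed: int = 0) -> ExpressionMatrix:
    """I.i.d. standard-normal matrix: the no-structure null."""
    if n_features < 1 or n_samples < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_features, n_samples))
    return ExpressionMatrix(
        tuple(f"N_{i:05d}" for i in range(n_features)),
        tuple(f"S{j:04d}" for j in range(n_samples)),
        values,
    )


def _design_dict(design: PlantedDesign) -> dict:
    return {
        "n_samples": design.n_samples,
        "module_sizes": list(design.module_sizes),
        "within_cor": design.within_cor,
        "n_background": design.n_background,
        "noise_sd": design.noise_sd,
        "loading_sd": design.loading_sd,
        "seed": design.seed,
    }
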