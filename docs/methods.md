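# Methods

## The stability model

A gene module is treated as a simple set of feature identifiers; everything
downstream is set arithmetic.  Stability is defined operationally: discover
a reference module set from the full matrix, re-discover on B bootstrap
re-samplings of the samples, score each reference module against each
replicate set by its best-match similarity, and summarise the B scores per
module with the H-index

    H(q) = max { h : (1/B) · #{ j : R_j ≥ h } ≥ h }.

Computationally, with scores sorted descending s(1) ≥ … ≥ s(B), the H-index
equals max_j min(s(j), j/B); the test suite checks this against a
brute-force grid search.  The H-index is monotone in every single score and
invariant to score order.

Assumptions worth stating:

* the discovery algorithm is deterministic given data and seed, so that all
  variation across replicates comes from the resampling;
* bootstrap duplicates are retained as distinct columns (standard bootstrap
  semantics); the duplicated sample ids are suffixed to keep identifiers
  unique;
* a replicate on which discovery fails (zero modules) scores 0 for every
  reference module, keeping B constant across modules — dropping failures
  would bias H upward.  The run aborts only if more than half the
  replicates fail.

The default scoring measure is the min-overlap (Simpson-analogue)
similarity, chosen because exact-subset rediscovery should count as a
perfect match from a stability standpoint; Jaccard and accuracy are
selectable wherever a measure is accepted.

## Discovery algorithms

**Weighted co-expression (`wgcna_like`).**  Unsigned Pearson adjacency
a_ij = |cor(x_i, x_j)|^β, topological-overlap similarity, average-linkage
hierarchical clustering of the dissimilarity, static cut, clusters below
`min_module_size` (default 50) moved to the unassigned remainder.
Zero-variance features are excluded up front with a warning.

*Cut-height semantics.*  The raw 1 − TOM scale has no portable meaning for
a static cut: within-module dissimilarities rarely fall below ~0.6 even at
within-module correlation 0.8, so a literal absolute cut at the default
0.15 would produce only singletons.  By default the pairwise
dissimilarities are therefore mapped to their empirical quantiles before
clustering (`normalize_dissimilarity=True`).  Under average linkage a cut
at height h then keeps groups whose mutual dissimilarities average inside
the smallest fraction h of all gene pairs — a scale-free criterion that
behaves identically whether the dissimilarity is 1 − TOM or
1 − adjacency.  The consequence, and the method's applicability condition:
coherent (within-module) pairs must make up less than the cut height's
share of all pairs, i.e. with a cut of 0.15 at most roughly √0.15 ≈ 39 % of
genes can sit in one module, and proportionally less across several.
Matrices that are almost entirely structured need a larger cut height.
Setting `normalize_dissimilarity=False` restores the literal absolute cut
for users who want the raw scale.

*Soft power.*  Default β = 6 (the common unsigned-network convention);
`soft_power="auto"` picks the smallest power in 1–12 whose scale-free fit
R² (log-frequency vs log-binned-connectivity regression over 10 equal-width
bins) reaches 0.8, falling back to the best-fitting candidate with a
warning.

**K-means (`kmeans_chaussabel`).**  Genes are points in sample space,
Euclidean distance, `n_starts` (default 10) explicit single-init runs with
per-start seeds spawned from the master seed; the minimal within-cluster
sum of squares is retained and all start WSS values are recorded in the
module-set provenance so the minimum can be audited.  Every gene is
assigned; the k-means engine relocates empty clusters internally, keeping k
fixed.  `k="elbow"` computes the proportion of variance explained
(between-cluster SS over total SS) along an ascending k range and returns
the first k whose marginal gain over k − 1 drops below 0.01 (configurable);
if no gain falls that low the maximum of the range is returned with a
warning.  The elbow baseline at k − 1 of the first candidate uses the
analytic value PVE(1) = 0.

Third-party algorithms (e.g. a PLS-derived gene-gene interaction
clustering) plug in through `register_algorithm(name, fn)` and are then
usable everywhere a built-in is, including inside the bootstrap loop.

## Random-module baseline

For each requested size, modules are assembled by sampling features without
replacement from the universe, scored by best match against every bootstrap
module set from a fitted result, and summarised with the H-index.  The
default design is sizes 50–400 in steps of 50 with 100 modules per size
(sizes exceeding the universe are rejected).  The baseline answers: what
H-index does a gene set with no coherent signal reach purely through
incidental overlap with whatever modules the replicates produce?  Larger
random modules score higher (overlap with *some* replicate module becomes
likelier), so the baseline should always be read per size.

## Subsampling study

For each n in `n_values` and each of `outer_reps` draws: subsample n
columns without replacement, discover a reference set on the subsample, run
the bootstrap loop within it (`inner_bootstraps` replicates), record every
module's size and H-index.  Defaults mirror a cohort-size scan (n = 10, 20,
40, 80, 120, 160; 10 outer repetitions; 100 inner bootstraps).  Per-cell
seeds derive from the tuple (seed, n, rep) via `numpy` seed sequences, so
the table is reproducible and any cell can be recomputed in isolation.
Cells where discovery is undefined (e.g. fewer than 4 samples) are flagged
rows, not silent omissions.  The small-vs-large comparison
(`size_stability_test`) contrasts H-indexes of 1st- vs 4th-size-quartile
modules at a given n with a two-sided Wilcoxon rank-sum test — exact null
distribution when the combined group size is ≤ 20 and no ties are present,
continuity-corrected normal approximation otherwise.

## Topology and annotation

The gene network places an edge where |cor| ≥ mean + k_sd · sd over all
off-diagonal pairs (k_sd default 2), both moments computed on absolute
correlations (`signed_mean=True` switches the moments to signed values).
Per-module metrics are computed on the subgraph induced by the module's
members: mean degree divided by module size; the number of appearances of a
member strictly inside a shortest path between two other members, counting
every shortest path of every pair; and triangle count divided by C(|q|, 3).
Shortest paths deliberately do not leave the module: a module-level metric
should not depend on outside genes.  Modules with fewer than 3 members get
a missing triad density.  Associations with the H-index use Spearman rank
correlation with two-sided p-values; constant inputs are reported missing
rather than as spurious coefficients.

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ overlap) with the module-set universe (all measured features, after
any identifier mapping) as the population; gene sets are intersected with
the universe before testing (configurable off).  The annotatability of a
module in a collection is Σ −log₁₀ p over the collection's sets, computed
on raw p-values; a Benjamini–Hochberg column is emitted in the per-set
table as a convenience but never enters the score.  P-values that underflow
are clamped to the smallest positive double.

## Synthetic data

The planted-module generator drives each module with one standard-normal
latent factor: member genes are √w · factor + √(1 − w) · ε with ε i.i.d.
normal, so the expected within-module correlation is exactly w and
cross-module/background correlations are 0.  Defaults: 3 modules of 60
genes, w = 0.8, 180 background noise genes, 100 samples.  The background
share keeps the generator in the regime where most genes are unstructured —
both the realistic case for genome-scale matrices and inside the
quantile-cut applicability condition above.  A `loading_sd` option spreads
per-gene loadings for harder recovery problems.  The generator emulates
block-correlation structure only: no probe effects, batch structure,
heavy-tailed noise, overlapping or nested modules.  Tests passing on this
data therefore demonstrate correctness of the machinery and qualitative
behaviours (stability rising with sample size, random modules scoring far
below coherent ones, annotatable modules being the stable ones), not
performance on real tissue data.

## Numerical and reproducibility choices

* One master seed per run; per-replicate and per-start seeds spawn from it
  via `numpy.random.SeedSequence`, so serial and parallel execution give
  identical results, and every CLI output embeds its seed and parameters in
  a `#`-prefixed JSON provenance header (identical argv + seed ⇒
  byte-identical files).
* Best-match ties break to the first module in stored order and are logged
  at debug level.
* Problem sizes in the shipped tests and the acceptance script are desk
  scale — hundreds of genes, ≤ 160 samples, B = 30–100 — chosen so the full
  pipeline, including 20-seed recovery sweeps, completes in minutes on one
  core while leaving the statistical conclusions unchanged; all defaults
  for production use (B = 1000, sizes 50–400) remain those stated above.

## Known limitations

* The quantile-normalised static cut cannot assign a very large fraction
  of the genome to modules (see applicability condition); dynamic tree
  cutting is out of scope.
* Module sets are hard partitions; overlapping or nested module structure
  is neither generated nor discovered.
* The random baseline conditions on one fitted bootstrap ensemble; its
  H-indexes are comparable across sizes within a fit, not across fits with
  different discovery settings.
* Shortest-path counts are exhaustive and scale poorly beyond a few
  hundred genes per module.
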