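# sabre — bootstrap stability of gene co-expression modules

Gene co-expression analyses (WGCNA-style weighted networks, k-means
clustering of transcripts, PLS-based interaction clustering, ...) partition
the measured genes into *modules* of coordinately expressed transcripts.
Which modules deserve follow-up?  A module whose membership evaporates when
a handful of subjects is swapped out is a poor candidate, yet standard
workflows report no such sensitivity measure, and an independent validation
cohort is rarely available.

`sabre` (Stability Assessment via Bootstrap RE-sampling) quantifies this
sensitivity without external data.  It is aimed at anyone running module
discovery on an expression matrix — microarray or RNA-seq, any discovery
algorithm that can be re-run on resampled samples.

## The procedure

1. Discover a **reference module set** Q = {q₁, …, qₙ} from the full
   features × samples matrix.
2. Draw B bootstrap re-samplings of the samples (with replacement) and
   re-run the same discovery algorithm on each, giving comparator sets Q⁽ʲ⁾.
3. For each reference module q and each replicate j, record the **best-match
   similarity** Rⱼ = max over q′ ∈ Q⁽ʲ⁾ of s(q, q′).  The default measure is

       s(q, q′) = |q ∩ q′| / min(|q|, |q′|),

   the Simpson-index analogue: a re-discovered module that is an exact
   subset of the reference counts as a perfect match.  Accuracy
   (|q ∩ q′| / |q|) and Jaccard (|q ∩ q′| / |q ∪ q′|) are also available.
4. Summarise each module's score distribution {Rⱼ} with the **H-index**:

       H(q) = max { h : (1/B) · #{ j : Rⱼ ≥ h } ≥ h } ∈ [0, 1],

   the largest h such that similarity ≥ h was observed in at least a
   fraction h of replicates.  H = 0.8 means: similarity of 0.8 or better in
   at least 80 % of bootstrap runs — a minimum-quality guarantee that a mean
   or a plain area-under-curve does not provide.

The package also ships the surrounding analyses: a random-module baseline
(what H-index does a randomly assembled gene set achieve?), a
subsample-then-bootstrap study of stability versus cohort size, per-module
network-connectivity metrics on a correlation-threshold graph, and
hypergeometric gene-set over-representation with a per-module
"annotatability" score (Σ −log₁₀ p over a collection).

## Worked example

```python
from sabre import SABRE, DiscoveryConfig, PlantedDesign, generate_planted

# synthetic matrix: 3 planted modules of 60 genes (within-module r = 0.8)
# on 180 background genes, 100 samples
x, truth = generate_planted(PlantedDesign(seed=1))

res = SABRE(x, DiscoveryConfig()).fit(n_boot=100, seed=1)
print(res)
```

```
SABRE stability (100 bootstraps, measure=min_overlap, seed=1, failed replicates=0)
module  size  h_index  mean_score  median_score  min_score
   W02    65    0.923       0.954         0.954      0.923
   W03    65    0.923       0.949         0.953      0.923
   W01    66    0.909       0.938         0.939      0.909
```

The discovery recovered the three planted blocks (W01–W03, named by size).
Each has H-index ≈ 0.92: in at least 92 % of the 100 bootstrap re-samplings
the re-discovered counterpart shared at least 92 % of the smaller module's
genes.  Compare the chance background:

```python
baseline = res.random_baseline(sizes=(60, 120), reps=20, seed=1)
# random modules of size 60:  median H-index 0.232
# random modules of size 120: median H-index 0.386
```

Randomly assembled gene sets plateau far below the planted modules — the
separation that makes the H-index a usable ranking criterion.

## Command line

Every step is also a subcommand of the `sabre` console script, with TSV
outputs carrying `#`-prefixed provenance headers (tool version, seed,
parameters) so identical seeds give byte-identical files:

```bash
sabre simulate --samples 100 --seed 1 --out-matrix m.tsv --out-truth t.tsv
sabre discover m.tsv --algorithm wgcna_like --seed 1 --out modules.tsv
sabre sabre m.tsv --bootstraps 1000 --seed 1 --out-h h.tsv --out-scores scores.tsv
sabre random-baseline m.tsv --bootstraps 1000 --seed 1 --out baseline.tsv
sabre subsample-study m.tsv --seed 1 --out study.tsv
sabre topology m.tsv modules.tsv --h-table h.tsv --out metrics.tsv
sabre annotate modules.tsv sets.gmt --out-sets enrich.tsv --out-scores annot.tsv
sabre compare reference.tsv other.tsv --out crosstab.tsv
```

Expression matrices are plain TSV (header row = sample ids, first column =
feature ids).  Gene sets use the GMT format.  Module sets use a small
versioned TSV: a `# sabre-module-set v1` magic line, a `# provenance: {...}`
JSON line, then one `feature_id<TAB>module` row per feature, with
unassigned features listed under the reserved label `_unassigned_`.

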