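# Methods

This note documents the models, numerical choices and limitations of
`autoclust`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Input transform

The pipeline's only preprocessing is the elementwise inverse hyperbolic
sine, `asinh(x) = ln(x + √(x²+1))`. It compresses large values like a
log while remaining defined at zero and on negative inputs (z-scores),
so no pseudocount is needed. It is strictly monotone and odd; identifiers
and matrix shape are preserved. Quality control, normalisation and batch
correction are deliberately out of scope and must precede the pipeline.

## Simulation model and feasibility

Simulated datasets are Gaussian class mixtures: every expression value
of a class-*j* sample is an independent draw from N(mean_j, sd_j), with
⌊n/c⌋ samples per class and the remainder in the last class. Two
parameterisations exist:

* *generic*: means are the floor of c evenly spaced reals on [5, 10c],
  SDs the floor of c evenly spaced reals on [1, 2c] (min 1). The floor
  of an evenly spaced real sequence is the only integerisation
  consistent with the published c = 5 values (5, 16, 27, 38, 50) /
  (1, 3, 5, 7, 10).
* *template*: class j has mean `m_input·10·j` and SD `sd_input·2·j`,
  scaled from an existing dataset's global mean/SD.

Feasibility analysis simulates a dataset of the requested dimensions and
scores bootstrap stability (spectral/rbf) for every k in
[max(2, c−2), c+2]. Class separation is summarised by the two-sided
Kolmogorov–Smirnov D between each pair of pooled class value
distributions (`scipy.stats.ks_2samp`).

The generator emulates dimensions, class imbalance and scale of real
expression matrices but **not** library-size effects, count noise,
gene–gene correlation or batch structure; a green simulation-based test
therefore establishes that the pipeline behaves correctly on idealised
class structure, not that it is robust to every artefact of real
RNA-seq. One master seed drives per-class substreams, so matrices are
bit-reproducible.

## Clustering engines

* **Spectral** (Ng–Jordan–Weiss): affinity from one of 7 kernels
  (rbfdot, polydot, tanhdot, laplacedot, vanilladot, anovadot,
  splinedot) with zeroed self-affinity; symmetric normalisation
  `D^{-1/2} A D^{-1/2}`; top-k eigenvectors; unit-norm rows; k-means on
  the embedding (10 restarts, best within-SS). Kernel widths use the
  median pairwise-distance heuristic — `σ = 1/median(d²)` for rbfdot,
  `1/median(d)` for laplacedot — computed from the data and echoed in
  reports. A deterministic width makes partitions reproducible; the
  upstream kernel library instead re-estimates widths from random
  subsamples on every call, which injects run-to-run noise (see
  *Limitations*).
* **k-means**: four classic update rules — Hartigan–Wong (1979 transfer
  criterion `n_s d_s/(n_s−1) − n_t d_t/(n_t+1)`), Lloyd and Forgy (two
  traditional names for the same batch rule; both kept as distinct pool
  entries), MacQueen (online centroid updates). Every call returns the
  best of 10 random initialisations by within-cluster SS: a single
  start is dominated by initialisation noise rather than by the update
  rule under comparison. Empty clusters trigger re-initialisation (10
  attempts) before erroring.
* **Hierarchical**: scipy's Lance–Williams agglomeration over 5
  distances (euclidean, manhattan, minkowski order 3, canberra with the
  0/0 := 0 convention, maximum) × 3 linkages (average, complete,
  median), cut with `fcluster(..., 'maxclust')`. Median linkage with a
  non-euclidean distance is formally improper and emits a warning; it
  stays available because the selection grid lists the combination.

All engines are pure functions of (matrix, parameters, seed) and return
1-based labels renumbered by first appearance; a dendrogram cut may
observe fewer than k clusters.

## Bootstrap stability

The data are clustered once, then B=25 times on resamples of n indices
drawn with replacement. The resample (a multiset) is clustered as-is;
each distinct sample inherits the label of its first occurrence. Every
original cluster, restricted to the samples present in the resample, is
matched to the resample cluster with the highest Jaccard similarity.
Per-cluster round means ("bootmeans") are combined by an unweighted
mean. Rounds whose resample holds fewer than k distinct samples are
skipped and logged. For spectral and hierarchical methods the full-data
kernel/distance matrix is computed once and subset per round (the kernel
width is therefore fixed across rounds); k-means re-runs on raw rows.

## Algorithm selection

Each comparison draws two *distinct* parameter settings from the
algorithm's pool (random with replacement across comparisons), runs both
at every k in the range with independently derived seeds, and records
the ARI (via scikit-learn, validated against an exhaustive pair-counting
oracle in the tests). The grand mean over (comparison × k) cells is the
algorithm's agreement; 3 comparisons is the default economy/precision
trade-off. Engine failures (e.g. the splinedot kernel overflowing on
large positive data, or non-positive affinity row sums under tanhdot)
invalidate only their cell; an algorithm with no valid cells is excluded
with a warning. Ties between algorithms break by the larger per-k
maximum, then by the fixed order spectral > k-means > hierarchical.

## Feature selection

Genes are ranked by descending unbiased (n−1) variance, ties stable by
gene ID. Nested prefixes of sizes step, 2·step, … (last prefix = all
genes) are each scored by mean bootstrap stability over the k range;
the highest average wins and ties go to the smaller set (fewer genes,
less noise). The default step of ⌈N/5⌉ yields five candidate sets.
"Re-drawing from the top of the ranked list" is implemented as nested
prefixes; duplicated columns would be degenerate.

## Choosing k

Partitions at every k in [2, kmax] are scored by 15 internal indexes.
Directions: maximised — Calinski–Harabasz, Dunn, PBM, Tau, Gamma,
silhouette; minimised — C-index, Davies–Bouldin, McClain–Rao, SD,
Ray–Turi, G+, S_Dbw, compactness (mean within-cluster pair distance),
connectivity (nearest-neighbour placement penalty, neighbourhood 10).
Compactness and connectivity are sometimes tabulated as "max" in the
literature this grid derives from, but their cited definitions are
minimised; the standard direction is used here. All index distances are
euclidean on the transformed, feature-selected matrix.

Numerical conventions: an index that cannot produce a finite score
(singleton clusters, zero denominators, a failed clustering at some k)
abstains at that k rather than raising; an index votes over its finite
scores and abstains entirely only when it has none. PBM is used exactly
as `(1/k)(E^T/E^W)·D_B` (some sources square it — vote-equivalent). The
SD index weight α is the average cluster scattering of the partition at
the largest k in the range. Tau uses the denominator
`√(N_B·N_W·N_T(N_T−1)/2)`. Within an index, score ties resolve toward
the larger k, as do vote-count ties, because overestimating k loses
less information than underestimating. Vote percentages are computed
over non-abstaining indexes; a unanimous single-k outcome is flagged as
potentially reflecting a biased dataset. Score curves are always
exported so users can audit individual indexes.

## Pipeline

Stage order: transform → feasibility (template-matched simulation with
c defaulting to the k-range upper bound; stability below the 0.60
threshold warns but does not abort) → algorithm selection → feature
selection with the selected algorithm's default parameterisation →
k voting → parameter tuning (bootstrap stability of every pool entry at
the chosen k; ties to the first in canonical pool order) → final
clustering. The second-ranked k estimate is always surfaced, and
`k_override` allows choosing it: a second estimate larger than the top
one can prevent merging small embedded subgroups. The result embeds all
stage reports and provenance (config, stage seeds, kernel widths) and
serialises to sorted-key JSON, so a re-run with the same matrix, config
and seed is byte-identical.

## Thresholds and defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_boot` | 25 | bootstrap rounds per stability score |
| `n_comparisons` | 3 | parameter pairs per algorithm in selection |
| `k_range` | [2, 6] | candidate cluster numbers |
| `feature_step` | ⌈N/5⌉ | prefix-size increment (5 candidate sets) |
| `stability_acceptable` | 0.60 | minimum advisable stability |
| `stability_strong` | 0.80 | very strong stability |
| connectivity neighbourhood | 10 | nearest neighbours scored |
| minkowski order | 3 | distinct from euclidean |

## Limitations

* The stability and agreement scores of this implementation are
  systematically *higher* on strongly clustered data than those of the
  R reference tooling this design descends from, because partitions here
  are deterministic given a seed: kernel widths come from a fixed median
  heuristic and embedding/k-means steps take the best of 10 restarts,
  whereas the reference re-estimates kernel widths from random
  subsamples inside every bootstrap round and clusters with single
  starts. On weakly structured data the scores agree closely; on
  well-separated classes this implementation reports near-perfect
  stability where noisier tooling saturates around 0.7–0.8.
* Inner-product kernels (vanilladot, polydot, tanhdot) are nearly
  rank-one on all-positive expression matrices and then carry little
  class information; their inclusion in the randomised pool lowers mean
  spectral agreement on positive data. splinedot overflows on large
  positive inputs and its cells are dropped with a logged error.
* Gaussian simulations do not model count overdispersion, gene–gene
  correlation or batch effects.
* Voting treats all non-abstaining indexes equally; strongly correlated
  indexes (the pair-counting family) can dominate.
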