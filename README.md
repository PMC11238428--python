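# autoclust

Stability-driven automated clustering of gene-expression matrices.

Cohort transcriptomic studies (bulk RNA-seq, microarray, single-cell)
routinely look for molecular subgroups of samples, but every step of an
unsupervised analysis — is this dataset clusterable at all? which
algorithm? which genes? how many clusters? — normally requires machine
learning expertise and ad-hoc experimentation. `autoclust` automates
those decisions with quality metrics computed from the data alone:

1. **Feasibility** — simulate Gaussian-class datasets matched to the
   input's dimensions and score their bootstrap cluster stability; low
   stability warns that a dataset of this shape cannot support robust
   clustering.
2. **Algorithm selection** — for spectral clustering (7 kernels),
   k-means (4 update rules) and hierarchical clustering (5 distances x 3
   linkages), measure the *intra-method agreement*: the mean adjusted
   Rand index (ARI) between runs of the same algorithm under randomly
   drawn distinct parameter pairs, over a range of k. An algorithm that
   partitions consistently when its own parameters change is being
   driven by structure in the data, not by its defaults.
3. **Feature selection** — rank genes by cross-sample variance, build
   nested top-of-ranking prefixes, and keep the prefix whose clusters
   are the most stable under bootstrap resampling.
4. **Number of clusters** — cluster at every k in `[2, kmax]` and let 15
   internal validity indexes (Calinski–Harabasz, Dunn, PBM, Tau, Gamma,
   C-index, Davies–Bouldin, McClain–Rao, SD, Ray–Turi, G+, silhouette,
   S_Dbw, compactness, connectivity) each vote for the k that optimises
   it; ties resolve toward larger k (overestimating loses less
   information than underestimating).
5. **Final clustering** — tune the selected algorithm's parameter by
   bootstrap stability at the chosen k and emit one cluster label per
   sample.

## Core statistics

**Bootstrap cluster stability.** Cluster the data once; for each of B=25
nonparametric bootstrap resamples, re-cluster and match every original
cluster to the most similar resample cluster by Jaccard similarity
`J(A, B) = |A∩B| / |A∪B|`, evaluated on the de-duplicated samples
present in the resample. The per-cluster means over rounds are averaged
into one score in [0, 1]; ≥ 0.6 is considered acceptable, ≥ 0.8 strong.

**Adjusted Rand index.** The chance-corrected pair-counting agreement
`ARI = (Index − E[Index]) / (max Index − E[Index])`; 1 for identical
partitions, ≈ 0 for random ones.

**Class separation (simulations).** The two-sided Kolmogorov–Smirnov
statistic `D = sup_x |F₁(x) − F₂(x)|` between each pair of pooled class
distributions.

## Worked example

```bash
autoclust simulate --samples 150 --genes 120 --classes 3 --seed 7 \
    --out-matrix expr.csv --out-labels labels.csv
autoclust run --matrix expr.csv --kmax 6 --seed 7 --out-dir results
```

prints

```
class means: (5.0, 17.0, 30.0); SDs: (1.0, 3.0, 6.0)
chosen algorithm: hierarchical; features: 96; k = 3 (top estimate 3, second 2); method: hierarchical/euclidean+average
```

The three simulated classes are strongly separated, so every stage is
confident: the feasibility simulation scores 0.90 average / 1.00 maximum
stability (well above the 0.60 threshold); hierarchical clustering shows
the highest intra-method agreement (0.91 vs 0.86 for k-means and 0.68
for spectral); the 96 most variable genes give the most stable clusters
(0.92); 7 of 15 indexes vote k = 3; and the final memberships in
`results/memberships.csv` match the simulated classes exactly
(ARI = 1.0 against `labels.csv`). `results/pipeline_report.json` records
every stage plus the seeds and kernel widths needed to re-run
bit-identically.

The same stages are available programmatically
(`autoclust.run_pipeline`, `autoclust.bootstrap_stability`,
`autoclust.select_method`, `autoclust.vote_k`, ...) and as the
subcommands `simulate`, `feasibility`, `select-method`,
`select-features`, `estimate-k` and `tune`.

## Reproduction script

`scripts/acceptance.py` re-measures the package's headline
simulated-data figures from scratch — single-class and five-class
stability profiles, intra-method agreement, Kolmogorov–Smirnov class
separation, variance-ranked feature choice, index voting, and recovery
of known memberships — averaging stochastic quantities over 10 replicate
seeds:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one `{"value": ..., "n": ...}` entry per figure and takes a
few minutes on a single CPU.
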