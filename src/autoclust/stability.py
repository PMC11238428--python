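"""Bootstrap cluster-stability scoring.

The workhorse metric of the toolkit: a partition is stable when each of
its clusters can be recovered from nonparametric bootstrap resamples of
the samples.  For every resample the data are re-clustered with the same
method and each original cluster is matched to the resample cluster with
the highest Jaccard similarity, evaluated on the de-duplicated set of
original samples present in the resample.  The per-cluster averages over
resampling rounds ("bootmeans") are combined by an unweighted mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .engines import (
    EngineError,
    MethodSpec,
    Partition,
    _as_matrix,
    _hierarchical_from_distances,
    cluster,
    default_method,
    kernel_matrix,
    kmeans_cluster,
    pairwise_distance,
    spectral_cluster_from_affinity,
)

__all__ = ["StabilityConfig", "StabilityProfile", "jaccard", "bootstrap_stability", "stability_over_ks"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StabilityConfig:
    """Bootstrap settings: 25 resampling rounds by default."""

    n_boot: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass(eq=False)
class StabilityProfile:
    """Per-k mean stability plus per-cluster bootmeans."""

    k_values: list[int]
    mean_stability: list[float]
    per_cluster: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.mean_stability):
            raise ValueError("k_values and mean_stability lengths differ")
        for s in self.mean_stability:
            if not 0.0 <= s <= 1.0 + 1e-12:
                raise ValueError(f"stability {s} outside [0, 1]")

    @property
    def stability_avg(self) -> float:
        return float(np.mean(self.mean_stability))

    @property
    def stability_max(self) -> float:
        return float(np.max(self.mean_stability))

    def to_report(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "mean_stability": [float(s) for s in self.mean_stability],
            "per_cluster": [[float(v) for v in row] for row in self.per_cluster],
            "stability_avg": self.stability_avg,
            "stability_max": self.stability_max,
        }


def jaccard(a, b) -> float:
    """|a & b| / |a | b| for index sets; 0 when both are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _resample_clusterer(X: np.ndarray, method: MethodSpec, k: int):
    """Return a closure clustering a bootstrap index vector.

    For spectral and hierarchical methods the full-data kernel/distance
    matrix is computed once (kernel width fixed from the full data) and
    subset per resample; k-means re-runs on the raw resampled rows.
    """
    if method.algorithm == "spectral":
        A = kernel_matrix(X, method.kernel)

        def run(ix: np.ndarray, seed: int) -> Partition:
            return spectral_cluster_from_affinity(A[np.ix_(ix, ix)], k, seed=seed)

    elif method.algorithm == "hierarchical":
        D = pairwise_distance(X, method.distance)

        def run(ix: np.ndarray, seed: int) -> Partition:
            return _hierarchical_from_distances(D[np.ix_(ix, ix)], k, method.distance, method.linkage)

    else:

        def run(ix: np.ndarray, seed: int) -> Partition:
            return kmeans_cluster(X[ix], k, variant=method.variant, seed=seed)

    return run


def bootstrap_stability(
    X,
    method: MethodSpec | None = None,
    k: int = 2,
    cfg: StabilityConfig | None = None,
) -> tuple[float, list[float]]:
    """Mean and per-cluster bootstrap stability of clustering ``X`` at ``k``.

    Returns ``(mean, per_cluster)`` where ``per_cluster[j]`` is the
    bootmean of original cluster ``j`` and ``mean`` is their unweighted
    average.  Rounds whose resample holds fewer than ``k`` distinct
    samples are skipped (and logged); if every round is skipped an
    :class:`EngineError` is raised.
    """
    X = _as_matrix(X)
    method = method or default_method("spectral")
    cfg = cfg or StabilityConfig()
    if k < 2:
        raise ValueError("stability is defined for k >= 2")
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    original = cluster(X, method, k, seed=int(rng.integers(2**31)))
    orig_sets = [set(c) for c in original.clusters()]
    run = _resample_clusterer(X, method, k)

    sums = np.zeros(len(orig_sets))
    rounds_done = 0
    for b in range(cfg.n_boot):
        ix = rng.integers(0, n, size=n)
        round_seed = int(rng.integers(2**31))
        uniq, first = np.unique(ix, return_index=True)
        if uniq.size < k:
            logger.warning("bootstrap round %d skipped: only %d distinct samples (< k=%d)", b, uniq.size, k)
            continue
        try:
            boot = run(ix, round_seed)
        except EngineError as exc:
            logger.warning("bootstrap round %d skipped: %s", b, exc)
            continue
        # label of each distinct original sample = label of its first occurrence
        boot_sets: dict[int, set[int]] = {}
        labels_u = boot.labels[first]
        for sample, lab in zip(uniq, labels_u):
            boot_sets.setdefault(int(lab), set()).add(int(sample))
        present = set(int(s) for s in uniq)
        for j, orig in enumerate(orig_sets):
            restricted = orig & present
            best = max((jaccard(restricted, bs) for bs in boot_sets.values()), default=0.0)
            sums[j] += best
        rounds_done += 1
    if rounds_done == 0:
        raise EngineError("all bootstrap rounds were skipped; cannot score stability")
    per_cluster = (sums / rounds_done).tolist()
    return float(np.mean(per_cluster)), per_cluster


def stability_over_ks(
    X,
    method: MethodSpec | None = None,
    k_range: tuple[int, int] = (2, 6),
    cfg: StabilityConfig | None = None,
) -> StabilityProfile:
    """Bootstrap stability for every ``k`` in the inclusive ``k_range``."""
    X = _as_matrix(X)
    method = method or default_method("spectral")
    cfg = cfg or StabilityConfig()
    lo, hi = int(k_range[0]), int(k_range[1])
    n = X.shape[0]
    if lo < 2 or hi > n - 1 or lo > hi:
        raise ValueError(f"k_range {k_range} must lie within [2, n_samples-1]={[2, n - 1]}")
    ks, means, per_cluster = [], [], []
    base = np.random.SeedSequence(cfg.seed).spawn(hi - lo + 1)
    for i, k in enumerate(range(lo, hi + 1)):
        sub = StabilityConfig(n_boot=cfg.n_boot, seed=int(base[i].generate_state(1)[0] % 2**31))
        m, pc = bootstrap_stability(X, method, k, sub)
        ks.append(k)
        means.append(m)
        per_cluster.append(pc)
    return StabilityProfile(ks, means, per_cluster)
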