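"""Ensemble estimation of the number of clusters by index voting.

Fifteen internal cluster-validity indexes - label-free scores of
compactness and/or separation - are evaluated on partitions of the data
at every k in a candidate range.  Each index votes for the k that
optimises it in its preferred direction (max or min); the vote counts,
over the indexes able to produce a score, rank the candidate ks.  Ties
are broken toward the larger k: overestimating k loses less information
than underestimating it.

All distances are euclidean on the (transformed, feature-selected)
matrix.  An index that cannot produce a finite score abstains rather
than raising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

from .engines import EngineError, MethodSpec, Partition, _as_matrix, cluster, default_method

__all__ = ["INDEX_NAMES", "INDEX_DIRECTIONS", "VoteTable", "compute_index", "score_indexes", "vote_k"]

logger = logging.getLogger(__name__)

#: voting direction of every index ("max" = larger is better)
INDEX_DIRECTIONS = {
    "calinski_harabasz": "max",
    "dunn": "max",
    "pbm": "max",
    "tau": "max",
    "gamma": "max",
    "c_index": "min",
    "davies_bouldin": "min",
    "mcclain_rao": "min",
    "sd_dis": "min",
    "ray_turi": "min",
    "g_plus": "min",
    "silhouette": "max",
    "s_dbw": "min",
    "compactness": "min",
    "connectivity": "min",
}

INDEX_NAMES = tuple(INDEX_DIRECTIONS)

_CONNECTIVITY_NEIGHBORS = 10


class _Geometry:
    """Per-partition cached quantities shared by the index formulas."""

    def __init__(self, X: np.ndarray, partition: Partition):
        self.X = X
        self.labels = partition.labels
        self.k = partition.k_observed
        self.n = X.shape[0]
        self.clusters = partition.clusters()
        self.centroids = np.vstack([X[idx].mean(axis=0) for idx in self.clusters])
        self.G = X.mean(axis=0)
        self.condensed = pdist(X, metric="euclidean")
        self.D = squareform(self.condensed)
        iu = np.triu_indices(self.n, 1)
        within = self.labels[iu[0]] == self.labels[iu[1]]
        self.dw = self.condensed[within]
        self.db = self.condensed[~within]
        self.N_W = self.dw.size
        self.N_B = self.db.size
        self.N_T = self.N_W + self.N_B
        self.S_W = float(self.dw.sum())
        self.S_B = float(self.db.sum())
        self._pair_counts = None

    def pair_counts(self) -> tuple[int, int]:
        """(concordant, discordant): within/between distance pairs where
        the within distance is strictly smaller / strictly larger."""
        if self._pair_counts is None:
            db_sorted = np.sort(self.db)
            s_plus = int((self.N_B - np.searchsorted(db_sorted, self.dw, side="right")).sum())
            s_minus = int(np.searchsorted(db_sorted, self.dw, side="left").sum())
            self._pair_counts = (s_plus, s_minus)
        return self._pair_counts

    def scat(self) -> float:
        """Average cluster scattering: mean of ||var(C_j)|| / ||var(X)||."""
        denom = np.linalg.norm(self.X.var(axis=0))
        if denom == 0:
            return math.nan
        norms = [np.linalg.norm(self.X[idx].var(axis=0)) for idx in self.clusters]
        return float(np.mean(norms) / denom)


def _require_multiple_clusters(geom: _Geometry) -> None:
    if geom.k < 2:
        raise ValueError("index undefined for a single observed cluster")


def _calinski_harabasz(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    return float(calinski_harabasz_score(geom.X, geom.labels))


def _davies_bouldin(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    return float(davies_bouldin_score(geom.X, geom.labels))


def _silhouette(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    return float(silhouette_score(geom.D, geom.labels, metric="precomputed"))


def _dunn(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    diameters = [geom.D[np.ix_(idx, idx)].max() for idx in geom.clusters]
    max_diam = max(diameters)
    min_inter = float(geom.db.min())
    return min_inter / max_diam


def _pbm(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    E_T = float(np.linalg.norm(geom.X - geom.G, axis=1).sum())
    E_W = sum(
        float(np.linalg.norm(geom.X[idx] - geom.centroids[j], axis=1).sum())
        for j, idx in enumerate(geom.clusters)
    )
    D_B = float(pdist(geom.centroids).max())
    return (1.0 / geom.k) * (E_T / E_W) * D_B


def _tau(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    s_plus, s_minus = geom.pair_counts()
    denom = math.sqrt(geom.N_B * geom.N_W * (geom.N_T * (geom.N_T - 1) / 2.0))
    return (s_plus - s_minus) / denom


def _gamma(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    s_plus, s_minus = geom.pair_counts()
    return (s_plus - s_minus) / (s_plus + s_minus)


def _g_plus(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    _, s_minus = geom.pair_counts()
    return 2.0 * s_minus / (geom.N_T * (geom.N_T - 1))


def _c_index(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    d_sorted = np.sort(geom.condensed)
    s_min = float(d_sorted[: geom.N_W].sum())
    s_max = float(d_sorted[-geom.N_W :].sum())
    return (geom.S_W - s_min) / (s_max - s_min)


def _mcclain_rao(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    return (geom.N_B / geom.N_W) * (geom.S_W / geom.S_B)


def _ray_turi(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    wcss = sum(
        float(((geom.X[idx] - geom.centroids[j]) ** 2).sum())
        for j, idx in enumerate(geom.clusters)
    )
    min_sq_sep = float((pdist(geom.centroids) ** 2).min())
    return wcss / geom.n / min_sq_sep


def _sd_dis(geom: _Geometry, alpha: float | None = None) -> float:
    _require_multiple_clusters(geom)
    scat = geom.scat()
    cd = pdist(geom.centroids)
    d_max, d_min = float(cd.max()), float(cd.min())
    CD = squareform(cd)
    row_sums = CD.sum(axis=1)
    dis = (d_max / d_min) * float((1.0 / row_sums).sum())
    if alpha is None:
        alpha = scat
    return alpha * scat + dis


def _s_dbw(geom: _Geometry) -> float:
    _require_multiple_clusters(geom)
    scat = geom.scat()
    var_norms = [np.linalg.norm(geom.X[idx].var(axis=0)) for idx in geom.clusters]
    stdev = math.sqrt(sum(var_norms)) / geom.k
    if stdev == 0:
        return math.nan

    def density(point: np.ndarray, members: np.ndarray) -> int:
        return int((np.linalg.norm(geom.X[members] - point, axis=1) <= stdev).sum())

    total = 0.0
    k = geom.k
    for i in range(k):
        for j in range(i + 1, k):
            members = np.concatenate([geom.clusters[i], geom.clusters[j]])
            mid = (geom.centroids[i] + geom.centroids[j]) / 2.0
            denom = max(density(geom.centroids[i], members), density(geom.centroids[j], members))
            if denom > 0:
                total += density(mid, members) / denom
    dens_bw = 2.0 * total / (k * (k - 1))
    return scat + dens_bw


def _compactness(geom: _Geometry) -> float:
    """Mean intracluster (within-pair) distance."""
    _require_multiple_clusters(geom)
    return geom.S_W / geom.N_W


def _connectivity(geom: _Geometry) -> float:
    """Penalty for separating a point from its nearest neighbours: the
    j-th nearest neighbour in another cluster costs 1/j (neighbourhood
    size 10)."""
    _require_multiple_clusters(geom)
    L = min(_CONNECTIVITY_NEIGHBORS, geom.n - 1)
    order = np.argsort(geom.D, axis=1, kind="stable")
    total = 0.0
    for i in range(geom.n):
        neighbors = [j for j in order[i] if j != i][:L]
        for rank, j in enumerate(neighbors, start=1):
            if geom.labels[j] != geom.labels[i]:
                total += 1.0 / rank
    return total


_INDEX_FUNCS = {
    "calinski_harabasz": _calinski_harabasz,
    "dunn": _dunn,
    "pbm": _pbm,
    "tau": _tau,
    "gamma": _gamma,
    "c_index": _c_index,
    "davies_bouldin": _davies_bouldin,
    "mcclain_rao": _mcclain_rao,
    "sd_dis": _sd_dis,
    "ray_turi": _ray_turi,
    "g_plus": _g_plus,
    "silhouette": _silhouette,
    "s_dbw": _s_dbw,
    "compactness": _compactness,
    "connectivity": _connectivity,
}


def compute_index(name: str, X, partition: Partition, alpha: float | None = None) -> float:
    """One named index for one partition; NaN marks an abstention."""
    if name not in _INDEX_FUNCS:
        raise ValueError(f"unknown index {name!r}; choose from {INDEX_NAMES}")
    geom = _Geometry(_as_matrix(X), partition)
    return _score(name, geom, alpha)


def _score(name: str, geom: _Geometry, alpha: float | None) -> float:
    try:
        if name == "sd_dis":
            value = _sd_dis(geom, alpha)
        else:
            value = _INDEX_FUNCS[name](geom)
    except (ValueError, ZeroDivisionError, FloatingPointError) as exc:
        logger.debug("index %s abstained: %s", name, exc)
        return math.nan
    return value if math.isfinite(value) else math.nan


def score_indexes(X, partitions: dict[int, Partition | None], alpha: float | None = None) -> dict[str, dict[int, float]]:
    """Score every index on every partition (NaN for failed partitions)."""
    X = _as_matrix(X)
    geoms = {k: (_Geometry(X, p) if p is not None else None) for k, p in partitions.items()}
    scores: dict[str, dict[int, float]] = {}
    for name in INDEX_NAMES:
        scores[name] = {
            k: (_score(name, g, alpha) if g is not None else math.nan) for k, g in geoms.items()
        }
    return scores


@dataclass(eq=False)
class VoteTable:
    index_scores: dict[str, dict[int, float]]
    index_votes: dict[str, int | None]
    vote_counts: dict[int, int]
    ranked_estimates: list[tuple[int, float]]
    warnings: list[str] = field(default_factory=list)

    @property
    def top_estimate(self) -> int:
        return self.ranked_estimates[0][0]

    @property
    def second_estimate(self) -> int | None:
        return self.ranked_estimates[1][0] if len(self.ranked_estimates) > 1 else None

    @property
    def n_voting(self) -> int:
        return sum(self.vote_counts.values())

    def to_report(self) -> dict:
        return {
            "index_scores": {
                name: {str(k): (None if math.isnan(v) else float(v)) for k, v in curve.items()}
                for name, curve in self.index_scores.items()
            },
            "index_votes": {name: v for name, v in self.index_votes.items()},
            "vote_counts": {str(k): c for k, c in self.vote_counts.items()},
            "ranked_estimates": [[k, pct] for k, pct in self.ranked_estimates],
            "warnings": list(self.warnings),
        }


def vote_k(
    X,
    method: MethodSpec | None = None,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
) -> VoteTable:
    """Cluster at every k in range, score all indexes, and vote.

    Each non-abstaining index votes the k optimising its score in its
    preferred direction; its own ties resolve toward the larger k.
    Ranked estimates sort by vote count, count ties also toward the
    larger k, with percentages over the non-abstaining indexes.
    """
    X = _as_matrix(X)
    method = method or default_method("spectral")
    lo, hi = int(k_range[0]), int(k_range[1])
    n = X.shape[0]
    if lo < 2 or hi > n - 1 or lo > hi:
        raise ValueError(f"k_range {k_range} must lie within [2, n_samples-1]")
    streams = np.random.SeedSequence(seed).spawn(hi - lo + 1)
    partitions: dict[int, Partition | None] = {}
    for i, k in enumerate(range(lo, hi + 1)):
        try:
            partitions[k] = cluster(X, method, k, seed=int(streams[i].generate_state(1)[0] % 2**31))
        except EngineError as exc:
            logger.warning("clustering failed at k=%d: %s", k, exc)
            partitions[k] = None

    # sd_dis weight: average scattering of the partition at the greatest k
    alpha = None
    for k in sorted(partitions, reverse=True):
        if partitions[k] is not None:
            g = _Geometry(X, partitions[k])
            s = g.scat()
            if math.isfinite(s):
                alpha = s
            break
    scores = score_indexes(X, partitions, alpha=alpha)

    index_votes: dict[str, int | None] = {}
    for name, curve in scores.items():
        finite = {k: v for k, v in curve.items() if math.isfinite(v)}
        if not finite:
            index_votes[name] = None
            continue
        best = (max if INDEX_DIRECTIONS[name] == "max" else min)(finite.values())
        index_votes[name] = max(k for k, v in finite.items() if v == best)

    votes = [v for v in index_votes.values() if v is not None]
    if not votes:
        raise EngineError("every validity index abstained; cannot vote on k")
    vote_counts = {k: votes.count(k) for k in range(lo, hi + 1) if votes.count(k) > 0}
    ranked = sorted(vote_counts.items(), key=lambda kv: (-kv[1], -kv[0]))
    total = len(votes)
    ranked_estimates = [(k, 100.0 * c / total) for k, c in ranked]

    warn: list[str] = []
    if len(vote_counts) == 1:
        warn.append(
            "all voting indexes selected a single k; treat with caution, "
            "this can reflect a biased dataset"
        )
    return VoteTable(scores, index_votes, vote_counts, ranked_estimates, warn)
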