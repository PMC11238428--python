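"""The three clustering engines and their parameter pools.

Each engine is a pure function of (matrix, parameters, seed) returning a
:class:`Partition`.  The parameter pools mirror the selection grid used
throughout the toolkit:

* spectral clustering (Ng-Jordan-Weiss) over 7 kernels
  (rbfdot, polydot, tanhdot, laplacedot, vanilladot, anovadot, splinedot);
* k-means over 4 classic update rules
  (Hartigan-Wong, Lloyd, Forgy, MacQueen);
* agglomerative hierarchical clustering over 5 distances
  (euclidean, manhattan, minkowski, canberra, maximum) x 3 linkages
  (average, complete, median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _linkage
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "EngineError",
    "Partition",
    "MethodSpec",
    "KERNELS",
    "KMEANS_VARIANTS",
    "HIER_DISTANCES",
    "HIER_LINKAGES",
    "parameter_pool",
    "default_method",
    "pairwise_distance",
    "kernel_matrix",
    "default_kernel_hyperparams",
    "spectral_embedding",
    "spectral_cluster",
    "kmeans_cluster",
    "hierarchical_cluster",
    "cluster",
]

KERNELS = ("rbfdot", "polydot", "tanhdot", "laplacedot", "vanilladot", "anovadot", "splinedot")
KMEANS_VARIANTS = ("Hartigan-Wong", "Lloyd", "Forgy", "MacQueen")
HIER_DISTANCES = ("euclidean", "manhattan", "minkowski", "canberra", "maximum")
HIER_LINKAGES = ("average", "complete", "median")

_MINKOWSKI_ORDER = 3  # distinct from euclidean; the grid never states an order


class EngineError(RuntimeError):
    """A clustering engine could not produce a partition."""


@dataclass(eq=False)
class Partition:
    """Cluster label per sample for a requested number of clusters ``k``.

    Labels are renumbered to ``1..k_observed`` in order of first
    appearance; ``k_observed`` may fall below the requested ``k`` (e.g.
    after a dendrogram cut with ties).
    """

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        _, first = np.unique(self.labels, return_index=True)
        order = self.labels[np.sort(first)]
        remap = {lab: i + 1 for i, lab in enumerate(order)}
        self.labels = np.array([remap[lab] for lab in self.labels], dtype=int)
        self.k = int(self.k)
        if self.k_observed > self.k:
            raise ValueError(f"{self.k_observed} distinct labels exceed requested k={self.k}")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def k_observed(self) -> int:
        return int(self.labels.max())

    def clusters(self) -> list[np.ndarray]:
        """Member index arrays, one per observed cluster (1-based order)."""
        return [np.flatnonzero(self.labels == j + 1) for j in range(self.k_observed)]


@dataclass(frozen=True)
class MethodSpec:
    """A clustering algorithm plus one point of its parameter pool."""

    algorithm: str
    kernel: str | None = None
    variant: str | None = None
    distance: str | None = None
    linkage: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm == "spectral":
            if self.kernel not in KERNELS:
                raise ValueError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")
            if self.variant or self.distance or self.linkage:
                raise ValueError("spectral takes only a kernel parameter")
        elif self.algorithm == "kmeans":
            if self.variant not in KMEANS_VARIANTS:
                raise ValueError(f"unknown k-means variant {self.variant!r}; choose from {KMEANS_VARIANTS}")
            if self.kernel or self.distance or self.linkage:
                raise ValueError("kmeans takes only a variant parameter")
        elif self.algorithm == "hierarchical":
            if self.distance not in HIER_DISTANCES:
                raise ValueError(f"unknown distance {self.distance!r}; choose from {HIER_DISTANCES}")
            if self.linkage not in HIER_LINKAGES:
                raise ValueError(f"unknown linkage {self.linkage!r}; choose from {HIER_LINKAGES}")
            if self.kernel or self.variant:
                raise ValueError("hierarchical takes distance and linkage parameters")
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def label(self) -> str:
        if self.algorithm == "spectral":
            return f"spectral/{self.kernel}"
        if self.algorithm == "kmeans":
            return f"kmeans/{self.variant}"
        return f"hierarchical/{self.distance}+{self.linkage}"


def parameter_pool(algorithm: str) -> list[MethodSpec]:
    """The full parameter pool of an algorithm, in canonical order."""
    if algorithm == "spectral":
        return [MethodSpec("spectral", kernel=k) for k in KERNELS]
    if algorithm == "kmeans":
        return [MethodSpec("kmeans", variant=v) for v in KMEANS_VARIANTS]
    if algorithm == "hierarchical":
        return [
            MethodSpec("hierarchical", distance=d, linkage=l)
            for d in HIER_DISTANCES
            for l in HIER_LINKAGES
        ]
    raise ValueError(f"unknown algorithm {algorithm!r}")


def default_method(algorithm: str) -> MethodSpec:
    """The canonical default parameterisation of an algorithm."""
    return {
        "spectral": MethodSpec("spectral", kernel="rbfdot"),
        "kmeans": MethodSpec("kmeans", variant="Hartigan-Wong"),
        "hierarchical": MethodSpec("hierarchical", distance="euclidean", linkage="average"),
    }[algorithm]


def _as_matrix(X) -> np.ndarray:
    values = getattr(X, "values", X)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    return values


# ---------------------------------------------------------------------------
# distances and kernels
# ---------------------------------------------------------------------------

_SCIPY_METRIC = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "minkowski": "minkowski",
    "canberra": "canberra",  # scipy treats 0/0 coordinate terms as 0
    "maximum": "chebyshev",
}


def pairwise_distance(X, metric: str = "euclidean") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix for one of the pool metrics."""
    X = _as_matrix(X)
    if metric not in _SCIPY_METRIC:
        raise ValueError(f"unknown distance {metric!r}; choose from {HIER_DISTANCES}")
    kwargs = {"p": _MINKOWSKI_ORDER} if metric == "minkowski" else {}
    return squareform(pdist(X, metric=_SCIPY_METRIC[metric], **kwargs))


def default_kernel_hyperparams(X, kernel: str) -> dict:
    """Data-driven kernel hyperparameters.

    For the width-parameterised kernels the inverse width ``sigma`` comes
    from the median pairwise distance heuristic: ``1 / median(d^2)`` for
    rbfdot and ``1 / median(d)`` for laplacedot, with euclidean ``d`` over
    all sample pairs.  The remaining kernels use their conventional
    defaults (scale 1, offset 1, degree 1; anovadot sigma 1).
    """
    X = _as_matrix(X)
    if kernel in ("rbfdot", "laplacedot"):
        d = pdist(X, metric="euclidean")
        med = float(np.median(d)) if d.size else 1.0
        if med <= 0:
            med = 1.0
        sigma = 1.0 / med**2 if kernel == "rbfdot" else 1.0 / med
        return {"sigma": sigma}
    if kernel == "anovadot":
        return {"sigma": 1.0, "degree": 1}
    if kernel in ("polydot", "tanhdot"):
        return {"scale": 1.0, "offset": 1.0, **({"degree": 1} if kernel == "polydot" else {})}
    return {}


def kernel_matrix(X, kernel: str, hyperparams: dict | None = None) -> np.ndarray:
    """Finite symmetric kernel (affinity) matrix over the samples."""
    X = _as_matrix(X)
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    hp = default_kernel_hyperparams(X, kernel)
    if hyperparams:
        hp.update(hyperparams)
    with np.errstate(over="ignore", invalid="ignore"):
        if kernel == "vanilladot":
            K = X @ X.T
        elif kernel == "polydot":
            K = (hp["scale"] * (X @ X.T) + hp["offset"]) ** hp["degree"]
        elif kernel == "tanhdot":
            K = np.tanh(hp["scale"] * (X @ X.T) + hp["offset"])
        elif kernel == "rbfdot":
            K = np.exp(-hp["sigma"] * cdist(X, X, metric="sqeuclidean"))
        elif kernel == "laplacedot":
            K = np.exp(-hp["sigma"] * cdist(X, X, metric="euclidean"))
        elif kernel == "anovadot":
            K = np.zeros((X.shape[0], X.shape[0]))
            for f in range(X.shape[1]):
                diff = X[:, f, None] - X[None, :, f]
                K += np.exp(-hp["sigma"] * diff**2)
            K = K ** hp["degree"]
        else:  # splinedot
            K = np.ones((X.shape[0], X.shape[0]))
            for f in range(X.shape[1]):
                x = X[:, f, None]
                y = X[None, :, f]
                m = np.minimum(x, y)
                K *= 1.0 + x * y + x * y * m - (x + y) / 2.0 * m**2 + m**3 / 3.0
    K = (K + K.T) / 2.0
    if not np.isfinite(K).all():
        raise EngineError(f"non-finite affinity produced by kernel {kernel!r}")
    return K


# ---------------------------------------------------------------------------
# spectral clustering (Ng-Jordan-Weiss)
# ---------------------------------------------------------------------------

def spectral_embedding(A: np.ndarray, k: int) -> np.ndarray:
    """Unit-row-norm embedding from a zero-diagonal affinity matrix.

    Symmetric-normalised Laplacian form ``D^{-1/2} A D^{-1/2}``, top-k
    eigenvectors stacked as columns, rows renormalised to unit length.
    """
    n = A.shape[0]
    d = A.sum(axis=1)
    if np.any(d <= 0) or not np.isfinite(d).all():
        raise EngineError("affinity matrix has a non-positive row sum; cannot normalise")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = A * np.outer(inv_sqrt, inv_sqrt)
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=[n - k, n - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vecs / norms


def _kmeans_on_embedding(Y: np.ndarray, k: int, seed: int) -> np.ndarray:
    # 10 restarts, keep best within-cluster SS
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    return km.fit_predict(Y)


def spectral_cluster(
    X,
    k: int,
    kernel: str = "rbfdot",
    seed: int = 0,
    hyperparams: dict | None = None,
) -> Partition:
    """NJW spectral clustering with the named kernel affinity.

    Self-affinity is zeroed before the Laplacian normalisation; the final
    assignment comes from k-means (10 restarts) on the unit-norm
    eigenvector rows.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not 2 <= k < n:
        raise EngineError(f"spectral clustering requires 2 <= k < n_samples; got k={k}, n={n}")
    A = kernel_matrix(X, kernel, hyperparams)
    np.fill_diagonal(A, 0.0)
    Y = spectral_embedding(A, k)
    return Partition(_kmeans_on_embedding(Y, k, seed), k)


def spectral_cluster_from_affinity(A: np.ndarray, k: int, seed: int = 0) -> Partition:
    """Spectral partition from a precomputed kernel matrix (diagonal rezeroed)."""
    A = np.array(A, dtype=float, copy=True)
    n = A.shape[0]
    if not 2 <= k < n:
        raise EngineError(f"spectral clustering requires 2 <= k < n_samples; got k={k}, n={n}")
    np.fill_diagonal(A, 0.0)
    Y = spectral_embedding(A, k)
    return Partition(_kmeans_on_embedding(Y, k, seed), k)


# ---------------------------------------------------------------------------
# k-means variants
# ---------------------------------------------------------------------------

_INIT_RETRIES = 10
_MAX_ITER = 100


def _init_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    return X[rng.choice(X.shape[0], size=k, replace=False)].copy()


def _nearest(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return cdist(X, centers, metric="sqeuclidean").argmin(axis=1)


def _batch_kmeans(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Lloyd/Forgy batch iterations from random-observation centers."""
    for _ in range(_INIT_RETRIES):
        centers = _init_centers(X, k, rng)
        labels = None
        for _ in range(_MAX_ITER):
            new = _nearest(X, centers)
            counts = np.bincount(new, minlength=k)
            if (counts == 0).any():
                labels = None
                break
            for j in range(k):
                centers[j] = X[new == j].mean(axis=0)
            if labels is not None and np.array_equal(labels, new):
                break
            labels = new
        if labels is not None:
            return labels
    raise EngineError(f"k-means produced an empty cluster in {_INIT_RETRIES} initialisations")


def _macqueen_kmeans(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Online (MacQueen) updates: points reassigned one at a time, the two
    affected centroids recomputed after every move."""
    n = X.shape[0]
    for _ in range(_INIT_RETRIES):
        centers = _init_centers(X, k, rng)
        labels = _nearest(X, centers)
        counts = np.bincount(labels, minlength=k)
        if (counts == 0).any():
            continue
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
        for _ in range(_MAX_ITER):
            moved = False
            for i in range(n):
                s = labels[i]
                t = int(np.argmin(((centers - X[i]) ** 2).sum(axis=1)))
                if t != s and counts[s] > 1:
                    labels[i] = t
                    counts[s] -= 1
                    counts[t] += 1
                    centers[s] = X[labels == s].mean(axis=0)
                    centers[t] = X[labels == t].mean(axis=0)
                    moved = True
            if not moved:
                return labels
        return labels
    raise EngineError(f"k-means produced an empty cluster in {_INIT_RETRIES} initialisations")


def _hartigan_wong_kmeans(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Hartigan-Wong transfer stage: move a point when the size-corrected
    within-SS change ``n_s d_s/(n_s-1) - n_t d_t/(n_t+1)`` is positive."""
    n = X.shape[0]
    for _ in range(_INIT_RETRIES):
        centers = _init_centers(X, k, rng)
        labels = _nearest(X, centers)
        counts = np.bincount(labels, minlength=k)
        if (counts == 0).any():
            continue
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
        for _ in range(_MAX_ITER):
            moved = False
            for i in range(n):
                s = labels[i]
                if counts[s] <= 1:
                    continue
                d2 = ((centers - X[i]) ** 2).sum(axis=1)
                removal_gain = counts[s] * d2[s] / (counts[s] - 1)
                add_cost = counts * d2 / (counts + 1)
                add_cost[s] = np.inf
                t = int(np.argmin(add_cost))
                if add_cost[t] < removal_gain - 1e-12:
                    centers[s] = (centers[s] * counts[s] - X[i]) / (counts[s] - 1)
                    centers[t] = (centers[t] * counts[t] + X[i]) / (counts[t] + 1)
                    counts[s] -= 1
                    counts[t] += 1
                    labels[i] = t
                    moved = True
            if not moved:
                break
        return labels
    raise EngineError(f"k-means produced an empty cluster in {_INIT_RETRIES} initialisations")


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for j in np.unique(labels):
        block = X[labels == j]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def kmeans_cluster(
    X, k: int, variant: str = "Hartigan-Wong", seed: int = 0, n_restarts: int = 10
) -> Partition:
    """k-means with one of the classic update rules.

    Hartigan-Wong follows the 1979 transfer procedure; Lloyd and Forgy are
    the batch rule (two traditional names for the same updates) with
    random-observation initialisation; MacQueen updates centroids online.
    Every call takes the best of ``n_restarts`` random initialisations by
    within-cluster sum of squares, since a single start is dominated by
    initialisation noise.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise EngineError(f"k-means requires 2 <= k <= n_samples; got k={k}, n={n}")
    canon = {v.lower().replace("_", "-"): v for v in KMEANS_VARIANTS}
    variant_key = canon.get(str(variant).lower().replace("_", "-"))
    if variant_key is None:
        raise ValueError(f"unknown k-means variant {variant!r}; choose from {KMEANS_VARIANTS}")
    if k == n:
        return Partition(np.arange(1, n + 1), k)
    runner = {
        "Lloyd": _batch_kmeans,
        "Forgy": _batch_kmeans,
        "MacQueen": _macqueen_kmeans,
        "Hartigan-Wong": _hartigan_wong_kmeans,
    }[variant_key]
    best_labels, best_ss = None, np.inf
    errors: list[str] = []
    for stream in np.random.SeedSequence(seed).spawn(max(1, n_restarts)):
        try:
            labels = runner(X, k, np.random.default_rng(stream))
        except EngineError as exc:
            errors.append(str(exc))
            continue
        ss = _within_ss(X, labels)
        if ss < best_ss - 1e-12:
            best_labels, best_ss = labels, ss
    if best_labels is None:
        raise EngineError(errors[-1])
    return Partition(best_labels, k)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(X, k: int, distance: str = "euclidean", linkage: str = "average") -> Partition:
    """Agglomerative clustering (Lance-Williams updates) cut at ``k``."""
    X = _as_matrix(X)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise EngineError(f"hierarchical clustering requires 2 <= k <= n_samples; got k={k}, n={n}")
    if linkage not in HIER_LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {HIER_LINKAGES}")
    if k == n:
        return Partition(np.arange(1, n + 1), k)
    D = pairwise_distance(X, distance)
    return _hierarchical_from_distances(D, k, distance, linkage)


def _hierarchical_from_distances(D: np.ndarray, k: int, distance: str, linkage: str) -> Partition:
    if linkage == "median" and distance != "euclidean":
        warnings.warn(
            f"median linkage is formally defined for euclidean distances only; "
            f"applying Lance-Williams coefficients to {distance!r} distances",
            RuntimeWarning,
            stacklevel=2,
        )
    condensed = squareform(D, checks=False)
    with warnings.catch_warnings():
        if linkage == "median":
            warnings.simplefilter("ignore", scipy_cluster_warning())
        Z = _linkage(condensed, method=linkage)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Partition(labels, k)


def scipy_cluster_warning():
    from scipy.cluster.hierarchy import ClusterWarning

    return ClusterWarning


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def cluster(X, spec: MethodSpec, k: int, seed: int = 0) -> Partition:
    """Run the engine named by ``spec`` on ``X`` at ``k`` clusters."""
    if spec.algorithm == "spectral":
        return spectral_cluster(X, k, kernel=spec.kernel, seed=seed)
    if spec.algorithm == "kmeans":
        return kmeans_cluster(X, k, variant=spec.variant, seed=seed)
    return hierarchical_cluster(X, k, distance=spec.distance, linkage=spec.linkage)
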