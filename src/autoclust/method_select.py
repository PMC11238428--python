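"""Algorithm selection by intra-method partition agreement.

Without labels there is no accuracy to optimise, so the toolkit asks a
different question: does an algorithm partition the data the *same way*
when its free parameters change?  For each algorithm a small number of
random parameter pairs is drawn from its pool (distinct within a pair)
and the two runs are compared with the adjusted Rand index at every k in
the tested range.  The algorithm with the highest grand-mean agreement is
the one most plausibly driven by structure in the data rather than by
its own arbitrary choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .engines import EngineError, MethodSpec, Partition, cluster, parameter_pool

__all__ = [
    "AgreementConfig",
    "AlgorithmAgreement",
    "AgreementReport",
    "adjusted_rand_index",
    "sample_parameter_pair",
    "intramethod_agreement",
    "select_method",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("spectral", "kmeans", "hierarchical")
# fixed tie-break order (spectral first)
_TIE_ORDER = {"spectral": 0, "kmeans": 1, "hierarchical": 2}


@dataclass(frozen=True)
class AgreementConfig:
    n_comparisons: int = 3
    k_range: tuple[int, int] = (2, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")
        if self.k_range[0] < 2 or self.k_range[0] > self.k_range[1]:
            raise ValueError("k_range lower bound must be >= 2 and <= upper bound")


@dataclass(eq=False)
class AlgorithmAgreement:
    """Agreement summary of one algorithm: grand mean over (comparison, k)
    cells, per-k means, and the full comparison log."""

    algorithm: str
    mean: float
    per_k: dict[int, float]
    comparisons: list[dict] = field(default_factory=list)

    def __float__(self) -> float:
        return self.mean


@dataclass(eq=False)
class AgreementReport:
    per_algorithm: dict[str, AlgorithmAgreement]
    chosen: str

    def to_report(self) -> dict:
        return {
            "chosen": self.chosen,
            "per_algorithm": {
                name: {
                    "mean_agreement": agg.mean,
                    "per_k": {str(k): v for k, v in agg.per_k.items()},
                    "comparisons": agg.comparisons,
                }
                for name, agg in self.per_algorithm.items()
            },
        }


def adjusted_rand_index(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    l1 = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    l2 = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if l1.shape != l2.shape:
        raise ValueError(f"partitions label different sample counts: {l1.size} vs {l2.size}")
    return float(adjusted_rand_score(l1, l2))


def sample_parameter_pair(algorithm: str, rng: np.random.Generator) -> tuple[MethodSpec, MethodSpec]:
    """Two distinct parameter settings drawn from the algorithm's pool."""
    pool = parameter_pool(algorithm)
    if len(pool) < 2:
        raise ValueError(f"parameter pool of {algorithm!r} has fewer than 2 entries")
    i, j = rng.choice(len(pool), size=2, replace=False)
    return pool[int(i)], pool[int(j)]


def _agreement_detail(X, algorithm: str, cfg: AgreementConfig) -> AlgorithmAgreement:
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.k_range
    cells: dict[int, list[float]] = {k: [] for k in range(lo, hi + 1)}
    log: list[dict] = []
    for comp in range(cfg.n_comparisons):
        spec_a, spec_b = sample_parameter_pair(algorithm, rng)
        # distinct derived seeds so agreement reflects parameter changes,
        # not shared initialisation
        seed_a = int(rng.integers(2**31))
        seed_b = int(rng.integers(2**31))
        for k in range(lo, hi + 1):
            entry = {"comparison": comp, "k": k, "param_a": spec_a.label, "param_b": spec_b.label}
            try:
                pa = cluster(X, spec_a, k, seed=seed_a)
                pb = cluster(X, spec_b, k, seed=seed_b)
                ari = adjusted_rand_index(pa, pb)
                cells[k].append(ari)
                entry["ari"] = ari
            except EngineError as exc:
                logger.warning("agreement cell failed (%s, k=%d): %s", algorithm, k, exc)
                entry["error"] = str(exc)
            log.append(entry)
    all_cells = [v for vs in cells.values() for v in vs]
    if not all_cells:
        raise EngineError(f"all agreement cells failed for algorithm {algorithm!r}")
    per_k = {k: float(np.mean(vs)) for k, vs in cells.items() if vs}
    return AlgorithmAgreement(algorithm, float(np.mean(all_cells)), per_k, log)


def intramethod_agreement(X, algorithm: str, cfg: AgreementConfig | None = None) -> float:
    """Grand-mean ARI over randomized parameter-pair comparisons and k."""
    return _agreement_detail(X, algorithm, cfg or AgreementConfig()).mean


def select_method(X, cfg: AgreementConfig | None = None) -> AgreementReport:
    """Score all three algorithms and choose the most self-consistent one.

    Ties on the mean are broken by the larger per-k maximum, then by the
    fixed order spectral > kmeans > hierarchical.  An algorithm whose
    cells all fail is excluded with a warning.
    """
    cfg = cfg or AgreementConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(len(ALGORITHMS))
    results: dict[str, AlgorithmAgreement] = {}
    for algorithm, stream in zip(ALGORITHMS, streams):
        sub = AgreementConfig(cfg.n_comparisons, cfg.k_range, int(stream.generate_state(1)[0] % 2**31))
        try:
            results[algorithm] = _agreement_detail(X, algorithm, sub)
        except EngineError as exc:
            logger.warning("algorithm %s excluded from selection: %s", algorithm, exc)
    if not results:
        raise EngineError("no algorithm produced any successful agreement cell")
    chosen = max(
        results.values(),
        key=lambda a: (a.mean, max(a.per_k.values()), -_TIE_ORDER[a.algorithm]),
    ).algorithm
    return AgreementReport(results, chosen)
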