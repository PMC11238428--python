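"""Variance-ranked nested feature sets scored by bootstrap stability.

Genes that barely vary across samples cannot discriminate them, so genes
are ranked by descending sample variance and nested prefixes of the
ranking (sizes ``step, 2*step, ...`` up to all genes) are evaluated: each
prefix restricts the matrix to its genes, bootstrap stability is averaged
over the tested k range, and the prefix with the highest average wins
(ties go to the smaller set - fewer genes, less noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .engines import MethodSpec, default_method
from .io_transform import ExpressionMatrix
from .stability import StabilityConfig, stability_over_ks

__all__ = [
    "FeatureSelectionConfig",
    "FeatureSetEvaluation",
    "rank_genes_by_variance",
    "build_feature_sets",
    "evaluate_feature_sets",
]


@dataclass(frozen=True)
class FeatureSelectionConfig:
    """step=None means ceil(N/5), i.e. five candidate set sizes."""

    step: int | None = None
    k_range: tuple[int, int] = (2, 6)
    method: MethodSpec | None = None
    stability_cfg: StabilityConfig | None = None

    def resolved_step(self, n_genes: int) -> int:
        step = self.step if self.step is not None else ceil(n_genes / 5)
        if not 1 <= step <= n_genes:
            raise ValueError(f"step must be in [1, {n_genes}]; got {step}")
        return step


@dataclass(eq=False)
class FeatureSetEvaluation:
    size: int
    genes: list[str]
    per_k_stability: list[float]
    avg_stability: float

    def to_report(self) -> dict:
        return {
            "size": self.size,
            "genes": list(self.genes),
            "per_k_stability": [float(v) for v in self.per_k_stability],
            "avg_stability": float(self.avg_stability),
        }


def rank_genes_by_variance(X: ExpressionMatrix) -> list[str]:
    """Gene IDs sorted by descending unbiased sample variance; ties keep a
    stable order by gene ID."""
    if X.n_samples < 2:
        raise ValueError("variance ranking requires at least 2 samples")
    variances = X.values.var(axis=0, ddof=1)
    order = sorted(range(X.n_genes), key=lambda j: (-variances[j], X.gene_ids[j]))
    return [X.gene_ids[j] for j in order]


def build_feature_sets(ranked: list[str], step: int) -> list[list[str]]:
    """Nested top-of-ranking prefixes of sizes step, 2*step, ..., N.

    The final prefix always contains every gene even when N is not a
    multiple of the step.
    """
    n = len(ranked)
    if not 1 <= step <= n:
        raise ValueError(f"step must be in [1, {n}]; got {step}")
    sizes = list(range(step, n + 1, step))
    if sizes[-1] != n:
        sizes.append(n)
    return [ranked[:s] for s in sizes]


def evaluate_feature_sets(
    X: ExpressionMatrix,
    cfg: FeatureSelectionConfig | None = None,
) -> tuple[list[FeatureSetEvaluation], FeatureSetEvaluation]:
    """Score every nested prefix and return (evaluations, best)."""
    cfg = cfg or FeatureSelectionConfig()
    method = cfg.method or default_method("spectral")
    stab_cfg = cfg.stability_cfg or StabilityConfig()
    ranked = rank_genes_by_variance(X)
    prefixes = build_feature_sets(ranked, cfg.resolved_step(X.n_genes))
    streams = np.random.SeedSequence(stab_cfg.seed).spawn(len(prefixes))
    evaluations: list[FeatureSetEvaluation] = []
    for genes, stream in zip(prefixes, streams):
        sub = StabilityConfig(stab_cfg.n_boot, int(stream.generate_state(1)[0] % 2**31))
        profile = stability_over_ks(X.subset_genes(genes), method, cfg.k_range, sub)
        evaluations.append(
            FeatureSetEvaluation(len(genes), genes, profile.mean_stability, profile.stability_avg)
        )
    # ties toward the smaller set
    best = max(evaluations, key=lambda e: (e.avg_stability, -e.size))
    return evaluations, best
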