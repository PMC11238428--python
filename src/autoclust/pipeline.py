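"""End-to-end orchestration of the clustering stages.

Stage order: input transform -> clustering-feasibility simulation ->
algorithm selection by intra-method agreement -> variance-ranked feature
selection by stability -> index voting on k -> stability-based parameter
tuning -> final clustering.  The result embeds every stage report plus
enough provenance (seeds, kernel widths, configuration) to re-run
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .engines import (
    MethodSpec,
    Partition,
    cluster,
    default_kernel_hyperparams,
    parameter_pool,
)
from .feature_select import FeatureSelectionConfig, FeatureSetEvaluation, evaluate_feature_sets
from .io_transform import ExpressionMatrix, _jsonable, asinh_transform
from .k_vote import VoteTable, vote_k
from .method_select import AgreementConfig, AgreementReport, select_method
from .simulate import SimulationSpec, feasibility_analysis
from .stability import StabilityConfig, bootstrap_stability

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "tune_parameters", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; completed stage reports are preserved in .partial."""

    def __init__(self, message: str, partial: dict):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class PipelineConfig:
    k_range: tuple[int, int] = (2, 6)
    n_comparisons: int = 3
    feature_step: int | None = None
    n_boot: int = 25
    seed: int = 0
    transform: bool = True
    stability_acceptable: float = 0.60
    stability_strong: float = 0.80
    feasibility_classes: int | None = None  # None -> k_range upper bound
    k_override: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.stability_acceptable < 1 and 0 < self.stability_strong < 1):
            raise ValueError("stability thresholds must lie in (0, 1)")
        if self.k_range[0] != 2:
            raise ValueError("the candidate k range starts at 2")


@dataclass(eq=False)
class PipelineResult:
    feasibility: dict
    agreement: AgreementReport
    feature_evaluations: list[FeatureSetEvaluation]
    chosen_features: FeatureSetEvaluation
    votes: VoteTable
    tuned_method: MethodSpec
    tuned_stability: float
    chosen_k: int
    final: Partition
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def memberships(self, sample_ids: list[str]) -> list[tuple[str, int]]:
        return list(zip(sample_ids, self.final.labels.tolist()))

    def to_report(self) -> dict:
        return {
            "feasibility": self.feasibility,
            "agreement": self.agreement.to_report(),
            "feature_selection": {
                "evaluations": [
                    {"size": e.size, "avg_stability": float(e.avg_stability)}
                    for e in self.feature_evaluations
                ],
                "chosen": self.chosen_features.to_report(),
            },
            "k_voting": self.votes.to_report(),
            "tuning": {"method": self.tuned_method.label, "stability": float(self.tuned_stability)},
            "chosen_k": self.chosen_k,
            "final_labels": self.final.labels.tolist(),
            "warnings": list(self.warnings),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(_jsonable(self.to_report()), indent=2, sort_keys=True)


def tune_parameters(
    X,
    algorithm: str,
    k: int,
    genes: list[str] | None = None,
    stability_cfg: StabilityConfig | None = None,
) -> tuple[MethodSpec, float, list[dict]]:
    """Pick the pool parameter with the highest bootstrap stability at ``k``.

    Ties go to the first candidate in canonical pool order.  Returns
    (winner, its stability, per-candidate log).
    """
    if genes is not None and isinstance(X, ExpressionMatrix):
        X = X.subset_genes(genes)
    stability_cfg = stability_cfg or StabilityConfig()
    pool = parameter_pool(algorithm)
    streams = np.random.SeedSequence(stability_cfg.seed).spawn(len(pool))
    log: list[dict] = []
    best_spec, best_val = None, -np.inf
    for spec, stream in zip(pool, streams):
        sub = StabilityConfig(stability_cfg.n_boot, int(stream.generate_state(1)[0] % 2**31))
        try:
            mean, _ = bootstrap_stability(X, spec, k, sub)
        except Exception as exc:  # engine failure on this parameter only
            logger.warning("tuning candidate %s failed: %s", spec.label, exc)
            log.append({"method": spec.label, "error": str(exc)})
            continue
        log.append({"method": spec.label, "stability": mean})
        if mean > best_val + 1e-12:
            best_spec, best_val = spec, mean
    if best_spec is None:
        raise PipelineError(f"no {algorithm} parameter produced a stability score", {"tuning_log": log})
    return best_spec, float(best_val), log


def run_pipeline(X: ExpressionMatrix, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run all stages on a samples x genes matrix; pure in (matrix, config)."""
    cfg = cfg or PipelineConfig()
    stage_seeds = [
        int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(cfg.seed).spawn(6)
    ]
    partial: dict = {}
    warnings_list: list[str] = []
    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix(np.asarray(X, dtype=float))
    work = asinh_transform(X) if cfg.transform else X

    try:
        # 1. feasibility on a template-matched simulation
        c = cfg.feasibility_classes or cfg.k_range[1]
        spec = SimulationSpec(
            work.n_samples,
            work.n_genes,
            c,
            template_mean=float(work.values.mean()),
            template_sd=float(work.values.std(ddof=1)),
            seed=stage_seeds[0],
        )
        feas = feasibility_analysis(spec, StabilityConfig(cfg.n_boot, stage_seeds[0]))
        feas_report = {
            "simulated_classes": c,
            "profile": feas.profile.to_report(),
            "max_stability": feas.max_stability,
            "avg_stability": feas.avg_stability,
        }
        partial["feasibility"] = feas_report
        if feas.avg_stability < cfg.stability_acceptable:
            warnings_list.append(
                f"feasibility stability {feas.avg_stability:.2f} is below the acceptable "
                f"threshold {cfg.stability_acceptable:.2f}; clustering a dataset of these "
                f"dimensions may not be worthwhile"
            )

        # 2. algorithm selection
        agreement = select_method(
            work.values, AgreementConfig(cfg.n_comparisons, cfg.k_range, stage_seeds[1])
        )
        partial["agreement"] = agreement.to_report()
        algorithm = agreement.chosen

        # 3. feature selection with the selected algorithm (default parameters)
        from .engines import default_method

        evaluations, best = evaluate_feature_sets(
            work,
            FeatureSelectionConfig(
                cfg.feature_step,
                cfg.k_range,
                default_method(algorithm),
                StabilityConfig(cfg.n_boot, stage_seeds[2]),
            ),
        )
        partial["feature_selection"] = best.to_report()
        restricted = work.subset_genes(best.genes)

        # 4. k voting
        votes = vote_k(restricted.values, default_method(algorithm), cfg.k_range, seed=stage_seeds[3])
        partial["k_voting"] = votes.to_report()
        chosen_k = cfg.k_override if cfg.k_override is not None else votes.top_estimate
        if votes.second_estimate is not None:
            logger.info(
                "top k estimate %d; second estimate %d", votes.top_estimate, votes.second_estimate
            )

        # 5. parameter tuning + final clustering
        tuned, tuned_stab, tuning_log = tune_parameters(
            restricted, algorithm, chosen_k, stability_cfg=StabilityConfig(cfg.n_boot, stage_seeds[4])
        )
        final = cluster(restricted.values, tuned, chosen_k, seed=stage_seeds[5])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline stage failed: {exc}", partial) from exc

    provenance = {
        "version": __version__,
        "config": {
            "k_range": list(cfg.k_range),
            "n_comparisons": cfg.n_comparisons,
            "feature_step": cfg.feature_step,
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
            "transform": cfg.transform,
            "stability_acceptable": cfg.stability_acceptable,
            "stability_strong": cfg.stability_strong,
            "feasibility_classes": cfg.feasibility_classes,
            "k_override": cfg.k_override,
        },
        "stage_seeds": stage_seeds,
        "tuning_log": tuning_log,
    }
    if tuned.algorithm == "spectral":
        provenance["kernel_hyperparams"] = default_kernel_hyperparams(restricted.values, tuned.kernel)
    warnings_list.extend(votes.warnings)
    return PipelineResult(
        feasibility=feas_report,
        agreement=agreement,
        feature_evaluations=evaluations,
        chosen_features=best,
        votes=votes,
        tuned_method=tuned,
        tuned_stability=tuned_stab,
        chosen_k=chosen_k,
        final=final,
        warnings=warnings_list,
        provenance=provenance,
    )
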