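"""Gaussian-mixture dataset simulation and clustering-feasibility analysis.

Datasets with a known class structure are generated to answer one
question before any real analysis starts: can a dataset of *these*
dimensions, with *this many* putative classes, produce stable clusters at
all?  Each class draws every expression value i.i.d. from its own normal
distribution.  Two parameterisations are provided:

* **generic** - class means are the floor of ``c`` evenly spaced reals
  spanning ``[5, 10c]`` and class SDs the floor of ``c`` evenly spaced
  reals spanning ``[1, 2c]`` (minimum 1);
* **template** (data-based) - class ``j`` (1-based) has mean
  ``m_input * 10 * j`` and SD ``sd_input * 2 * j``, matching the scale of
  an existing dataset.

Class separation is summarised by the two-sided Kolmogorov-Smirnov D
statistic between each pair of pooled class distributions, and
feasibility by bootstrap stability over ``k in [max(2, c-2), c+2]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import ks_2samp

from .engines import Partition, default_method
from .io_transform import ExpressionMatrix
from .stability import StabilityConfig, StabilityProfile, stability_over_ks

__all__ = [
    "SimulationSpec",
    "ClassParameters",
    "SimulatedDataset",
    "KSReport",
    "FeasibilityResult",
    "generic_class_parameters",
    "template_class_parameters",
    "class_sizes",
    "simulate_dataset",
    "ks_pairwise",
    "ecdf_plot",
    "feasibility_k_range",
    "feasibility_analysis",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Dimensions and (optional) data-based template of a simulation."""

    n_samples: int
    n_genes: int
    n_classes: int
    template_mean: float | None = None
    template_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_samples, n_genes and n_classes must be positive")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if (self.template_mean is None) != (self.template_sd is None):
            raise ValueError("template_mean and template_sd must be given together")


@dataclass(frozen=True)
class ClassParameters:
    """Per-class normal means and standard deviations."""

    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must have equal length")
        if any(s <= 0 for s in self.sds):
            raise ValueError("class standard deviations must be strictly positive")

    @property
    def n_classes(self) -> int:
        return len(self.means)


@dataclass(eq=False)
class SimulatedDataset:
    matrix: ExpressionMatrix
    true_labels: Partition
    class_params: ClassParameters


@dataclass(eq=False)
class KSReport:
    """Pairwise two-sided KS D statistics between pooled class values."""

    pairwise_D: np.ndarray
    D_avg: float
    class_ids: list[int]


@dataclass(eq=False)
class FeasibilityResult:
    profile: StabilityProfile
    max_stability: float
    avg_stability: float
    dataset: SimulatedDataset

    def __iter__(self):
        return iter((self.profile, self.max_stability, self.avg_stability))


def generic_class_parameters(c: int) -> ClassParameters:
    """Evenly spaced integer class parameters: means span [5, 10c], SDs [1, 2c].

    "Evenly spaced integers" is realised as the floor of an evenly spaced
    real sequence, e.g. c=5 gives means (5, 16, 27, 38, 50) and SDs
    (1, 3, 5, 7, 10).
    """
    if c < 1:
        raise ValueError("number of classes must be >= 1")
    means = np.floor(np.linspace(5.0, 10.0 * c, c))
    sds = np.maximum(np.floor(np.linspace(1.0, 2.0 * c, c)), 1.0)
    return ClassParameters(tuple(means.tolist()), tuple(sds.tolist()))


def template_class_parameters(m_input: float, sd_input: float, c: int) -> ClassParameters:
    """Data-based class parameters: class j has mean m*10*j and SD sd*2*j."""
    if c < 1:
        raise ValueError("number of classes must be >= 1")
    if sd_input <= 0:
        raise ValueError("sd_input must be > 0")
    idx = np.arange(1, c + 1, dtype=float)
    return ClassParameters(tuple((m_input * 10.0 * idx).tolist()), tuple((sd_input * 2.0 * idx).tolist()))


def class_sizes(n: int, c: int) -> list[int]:
    """floor(n/c) samples per class; the remainder goes to the last class."""
    base = n // c
    sizes = [base] * c
    sizes[-1] += n - base * c
    return sizes


def _default_params(spec: SimulationSpec) -> ClassParameters:
    if spec.template_mean is not None:
        return template_class_parameters(spec.template_mean, spec.template_sd, spec.n_classes)
    return generic_class_parameters(spec.n_classes)


def simulate_dataset(spec: SimulationSpec, params: ClassParameters | None = None) -> SimulatedDataset:
    """Draw the simulated matrix: every value of a class-j sample is an
    independent N(mean_j, sd_j) draw.  Reproducible given ``spec.seed``
    (one master seed, per-class derived streams)."""
    params = params or _default_params(spec)
    if params.n_classes != spec.n_classes:
        raise ValueError(
            f"class parameters describe {params.n_classes} classes, spec requests {spec.n_classes}"
        )
    sizes = class_sizes(spec.n_samples, spec.n_classes)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_classes)
    blocks, labels = [], []
    for j, (mu, sd, nj) in enumerate(zip(params.means, params.sds, sizes)):
        rng = np.random.default_rng(streams[j])
        blocks.append(rng.normal(mu, sd, size=(nj, spec.n_genes)))
        labels.extend([j + 1] * nj)
    matrix = ExpressionMatrix(np.vstack(blocks))
    return SimulatedDataset(matrix, Partition(np.array(labels), spec.n_classes), params)


def _pooled_class_values(ds: SimulatedDataset) -> list[np.ndarray]:
    return [ds.matrix.values[idx].ravel() for idx in ds.true_labels.clusters()]


def ks_pairwise(ds: SimulatedDataset) -> KSReport:
    """Two-sided KS D between every pair of pooled class distributions."""
    pooled = _pooled_class_values(ds)
    c = len(pooled)
    if c < 2:
        raise ValueError("pairwise KS requires at least 2 classes")
    D = np.zeros((c, c))
    for i in range(c):
        for j in range(i + 1, c):
            D[i, j] = D[j, i] = ks_2samp(pooled[i], pooled[j]).statistic
    iu = np.triu_indices(c, 1)
    return KSReport(D, float(D[iu].mean()), list(range(1, c + 1)))


def ecdf_plot(ds: SimulatedDataset, path: str | Path) -> None:
    """Export the per-class empirical CDF curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for j, values in enumerate(_pooled_class_values(ds), start=1):
        x = np.sort(values)
        ax.step(x, np.arange(1, x.size + 1) / x.size, where="post", label=f"class {j}")
    ax.set_xlabel("expression value")
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def feasibility_k_range(c: int, n_samples: int) -> tuple[int, int]:
    """k in [number of classes - 2, number of classes + 2], floored at 2."""
    lo = max(2, c - 2)
    hi = min(c + 2, n_samples - 1)
    return lo, max(lo, hi)


def feasibility_analysis(
    spec: SimulationSpec,
    stability_cfg: StabilityConfig | None = None,
    params: ClassParameters | None = None,
    k_range: tuple[int, int] | None = None,
) -> FeasibilityResult:
    """Simulate a dataset of the requested dimensions and score its
    bootstrap stability (spectral/rbf) over the feasibility k range."""
    stability_cfg = stability_cfg or StabilityConfig(seed=spec.seed)
    ds = simulate_dataset(spec, params)
    if k_range is None:
        k_range = feasibility_k_range(spec.n_classes, spec.n_samples)
    profile = stability_over_ks(ds.matrix, default_method("spectral"), k_range, stability_cfg)
    return FeasibilityResult(profile, profile.stability_max, profile.stability_avg, ds)
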