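import numpy as np
import pytest

from autoclust import ExpressionMatrix, SimulationSpec, generic_class_parameters, simulate_dataset


@pytest.fixture(scope="session")
def two_blobs():
    """40 samples x 5 genes, two Gaussian classes at means 0 and 50 (sd 1)."""
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0.0, 1.0, (20, 5)), rng.normal(50.0, 1.0, (20, 5))])
    labels = np.repeat([1, 2], 20)
    return ExpressionMatrix(X), labels


@pytest.fixture(scope="session")
def three_blobs():
    """60 samples x 8 genes, three well-separated Gaussian classes."""
    rng = np.random.default_rng(11)
    X = np.vstack(
        [rng.normal(mu, 1.0, (20, 8)) for mu in (0.0, 30.0, 60.0)]
    )
    labels = np.repeat([1, 2, 3], 20)
    return ExpressionMatrix(X), labels


@pytest.fixture(scope="session")
def small_multiclass():
    """Down-scaled analogue of the five-class reference simulation."""
    return simulate_dataset(SimulationSpec(100, 40, 5, seed=3), generic_class_parameters(5))
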