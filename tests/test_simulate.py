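import numpy as np
import pytest
from scipy.stats import norm

from autoclust import (
    SimulationSpec,
    generic_class_parameters,
    ks_pairwise,
    simulate_dataset,
    template_class_parameters,
)
from autoclust.simulate import SimulatedDataset, class_sizes, feasibility_k_range


class TestClassParameters:
    @pytest.mark.parametrize(
        "c,means,sds",
        [
            (5, (5, 16, 27, 38, 50), (1, 3, 5, 7, 10)),
            (2, (5, 20), (1, 4)),
            (3, (5, 17, 30), (1, 3, 6)),
            (1, (5,), (1,)),
        ],
    )
    def test_generic_scheme(self, c, means, sds):
        params = generic_class_parameters(c)
        assert params.means == tuple(float(m) for m in means)
        assert params.sds == tuple(float(s) for s in sds)

    def test_generic_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            generic_class_parameters(0)

    @pytest.mark.parametrize(
        "m,sd,c,means,sds",
        [
            (0.5, 1.0, 3, (5, 10, 15), (2, 4, 6)),
            (2.0, 0.5, 1, (20,), (1,)),
            (0.0, 1.0, 2, (0, 0), (2, 4)),
        ],
    )
    def test_template_scheme(self, m, sd, c, means, sds):
        params = template_class_parameters(m, sd, c)
        assert params.means == tuple(float(x) for x in means)
        assert params.sds == tuple(float(s) for s in sds)

    def test_template_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            template_class_parameters(1.0, 0.0, 2)


class TestSimulateDataset:
    def test_class_sizes_remainder_to_last(self):
        assert class_sizes(359, 5) == [71, 71, 71, 71, 75]
        assert class_sizes(10, 2) == [5, 5]

    def test_single_class_dataset(self):
        ds = simulate_dataset(SimulationSpec(100, 100, 1, seed=0))
        assert ds.matrix.shape == (100, 100)
        assert ds.true_labels.k_observed == 1
        # one N(5, 1) Gaussian under the generic scheme
        assert ds.matrix.values.mean() == pytest.approx(5.0, abs=0.05)
        assert ds.matrix.values.std() == pytest.approx(1.0, abs=0.05)

    def test_labels_partition_counts(self):
        ds = simulate_dataset(SimulationSpec(103, 10, 5, seed=1))
        sizes = [len(c) for c in ds.true_labels.clusters()]
        assert sizes == [20, 20, 20, 20, 23]
        assert sum(sizes) == 103

    def test_seed_determinism(self):
        a = simulate_dataset(SimulationSpec(30, 6, 3, seed=42))
        b = simulate_dataset(SimulationSpec(30, 6, 3, seed=42))
        np.testing.assert_array_equal(a.matrix.values, b.matrix.values)
        c = simulate_dataset(SimulationSpec(30, 6, 3, seed=43))
        assert not np.array_equal(a.matrix.values, c.matrix.values)

    def test_template_invariants(self):
        with pytest.raises(ValueError):
            SimulationSpec(10, 5, 2, template_mean=1.0)  # sd missing
        with pytest.raises(ValueError):
            SimulationSpec(2, 5, 3)  # fewer samples than classes


class TestKS:
    def test_identical_and_disjoint(self, small_multiclass):
        from autoclust.engines import Partition
        from autoclust.io_transform import ExpressionMatrix

        same = ExpressionMatrix(np.tile(np.arange(10.0), (4, 1)))
        ds = SimulatedDataset(same, Partition(np.array([1, 1, 2, 2]), 2), None)
        rep = ks_pairwise(ds)
        assert rep.pairwise_D[0, 1] == 0.0
        disjoint = ExpressionMatrix(np.array([[0.0, 1.0], [0.5, 0.2], [10.0, 11.0], [10.5, 12.0]]))
        ds = SimulatedDataset(disjoint, Partition(np.array([1, 1, 2, 2]), 2), None)
        assert ks_pairwise(ds).pairwise_D[0, 1] == 1.0

    def test_two_gaussians_matches_analytic_D(self):
        # sup-norm distance between N(5,1) and N(16,3) CDFs on a fine grid
        x = np.linspace(-10, 40, 200001)
        analytic = np.max(np.abs(norm.cdf(x, 5, 1) - norm.cdf(x, 16, 3)))
        assert analytic == pytest.approx(0.995, abs=0.001)
        ds = simulate_dataset(SimulationSpec(100, 60, 2, seed=5), generic_class_parameters(2))
        # generic c=2 -> N(5,1) vs N(20,4); analytic D for that pair:
        analytic2 = np.max(np.abs(norm.cdf(x, 5, 1) - norm.cdf(x, 20, 4)))
        rep = ks_pairwise(ds)
        assert rep.pairwise_D[0, 1] == pytest.approx(analytic2, abs=0.01)
        assert rep.D_avg == rep.pairwise_D[0, 1]

    def test_single_class_rejected(self):
        ds = simulate_dataset(SimulationSpec(10, 4, 1, seed=0))
        with pytest.raises(ValueError):
            ks_pairwise(ds)


def test_feasibility_k_range_floors_at_two():
    assert feasibility_k_range(1, 100) == (2, 3)
    assert feasibility_k_range(5, 100) == (3, 7)
    assert feasibility_k_range(2, 100) == (2, 4)
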