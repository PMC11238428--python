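import numpy as np
import pytest

from autoclust import EngineError, MethodSpec, adjusted_rand_index, cluster, parameter_pool
from autoclust.engines import (
    HIER_DISTANCES,
    HIER_LINKAGES,
    KERNELS,
    KMEANS_VARIANTS,
    hierarchical_cluster,
    kernel_matrix,
    kmeans_cluster,
    pairwise_distance,
    spectral_cluster,
    spectral_embedding,
)

FOUR_POINTS = np.array([[0.0], [1.0], [10.0], [11.0]])


class TestDistancesAndKernels:
    def test_euclidean_identical_rows_zero(self):
        X = np.ones((3, 4))
        D = pairwise_distance(X, "euclidean")
        assert np.all(D == 0) and D.shape == (3, 3)

    def test_vanilladot_is_inner_product(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = kernel_matrix(X, "vanilladot")
        assert K[0, 1] == 0.0 and K[0, 0] == 1.0

    def test_rbf_self_affinity_one(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        K = kernel_matrix(X, "rbfdot")
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    def test_canberra_zero_pair_convention(self):
        # 0/0 coordinate terms contribute 0
        X = np.array([[0.0, 1.0], [0.0, 3.0]])
        D = pairwise_distance(X, "canberra")
        assert D[0, 1] == pytest.approx(0.5)

    def test_unknown_names_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="euclidean"):
            pairwise_distance(X, "cosine")
        with pytest.raises(ValueError, match="rbfdot"):
            kernel_matrix(X, "gaussian")

    def test_splinedot_overflow_names_kernel(self):
        X = np.full((30, 200), 50.0) + np.random.default_rng(1).normal(size=(30, 200))
        with pytest.raises(EngineError, match="splinedot"):
            kernel_matrix(X, "splinedot")


class TestSpectral:
    def test_recovers_two_blobs(self, two_blobs):
        em, truth = two_blobs
        p = spectral_cluster(em.values, 2, "rbfdot", seed=0)
        assert adjusted_rand_index(p.labels, truth) == 1.0

    def test_embedding_rows_unit_norm(self, two_blobs):
        em, _ = two_blobs
        A = kernel_matrix(em.values, "rbfdot")
        np.fill_diagonal(A, 0.0)
        Y = spectral_embedding(A, 3)
        np.testing.assert_allclose(np.linalg.norm(Y, axis=1), 1.0, atol=1e-10)

    def test_k_bounds(self, two_blobs):
        em, _ = two_blobs
        with pytest.raises(EngineError):
            spectral_cluster(em.values, em.n_samples, "rbfdot")
        with pytest.raises(EngineError):
            spectral_cluster(em.values, 1, "rbfdot")

    def test_seed_determinism(self, two_blobs):
        em, _ = two_blobs
        a = spectral_cluster(em.values, 2, "laplacedot", seed=5)
        b = spectral_cluster(em.values, 2, "laplacedot", seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestKMeans:
    @pytest.mark.parametrize("variant", KMEANS_VARIANTS)
    def test_exact_two_partition(self, variant):
        # exhaustive over 2-partitions of {0,1,10,11}: {0,1}|{10,11} minimises within-SS
        p = kmeans_cluster(FOUR_POINTS, 2, variant, seed=0)
        assert p.labels[0] == p.labels[1] != p.labels[2] == p.labels[3]

    def test_k_equals_n_singletons(self):
        p = kmeans_cluster(FOUR_POINTS, 4, "Lloyd", seed=0)
        assert sorted(p.labels) == [1, 2, 3, 4]

    @pytest.mark.parametrize("variant", KMEANS_VARIANTS)
    def test_seed_determinism(self, variant, three_blobs):
        em, _ = three_blobs
        a = kmeans_cluster(em.values, 3, variant, seed=9)
        b = kmeans_cluster(em.values, 3, variant, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_recovers_three_blobs(self, three_blobs):
        em, truth = three_blobs
        for variant in KMEANS_VARIANTS:
            p = kmeans_cluster(em.values, 3, variant, seed=1)
            assert adjusted_rand_index(p.labels, truth) == 1.0, variant


class TestHierarchical:
    def test_manual_dendrogram_cut(self):
        p = hierarchical_cluster(FOUR_POINTS, 2, "euclidean", "average")
        assert p.labels[0] == p.labels[1] != p.labels[2] == p.labels[3]

    def test_k_equals_n_singletons(self):
        p = hierarchical_cluster(FOUR_POINTS, 4, "euclidean", "complete")
        assert sorted(p.labels) == [1, 2, 3, 4]

    @pytest.mark.parametrize("distance", HIER_DISTANCES)
    @pytest.mark.parametrize("linkage", HIER_LINKAGES)
    def test_full_grid_valid_partitions(self, distance, linkage, three_blobs):
        em, _ = three_blobs
        X = em.values + 1.0  # canberra needs a sign-stable domain
        with pytest.warns(RuntimeWarning) if (linkage == "median" and distance != "euclidean") else np.testing.suppress_warnings():
            p = hierarchical_cluster(X, 3, distance, linkage)
        assert p.n == em.n_samples and 1 <= p.k_observed <= 3

    def test_unsupported_pair_rejected(self, three_blobs):
        em, _ = three_blobs
        with pytest.raises(ValueError):
            hierarchical_cluster(em.values, 2, "euclidean", "ward")


class TestPoolsAndDispatch:
    def test_pool_sizes(self):
        assert len(parameter_pool("spectral")) == len(KERNELS) == 7
        assert len(parameter_pool("kmeans")) == len(KMEANS_VARIANTS) == 4
        assert len(parameter_pool("hierarchical")) == len(HIER_DISTANCES) * len(HIER_LINKAGES) == 15

    def test_methodspec_validation(self):
        with pytest.raises(ValueError):
            MethodSpec("spectral", kernel="nope")
        with pytest.raises(ValueError):
            MethodSpec("kmeans", kernel="rbfdot")
        with pytest.raises(ValueError):
            MethodSpec("svm")

    def test_relabeling_invariance(self, three_blobs):
        em, truth = three_blobs
        p = cluster(em.values, MethodSpec("kmeans", variant="MacQueen"), 3, seed=2)
        shuffled = ((p.labels + 1) % 3) + 1  # a pure relabeling
        assert adjusted_rand_index(p.labels, shuffled) == 1.0
        assert adjusted_rand_index(p.labels, truth) == 1.0
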