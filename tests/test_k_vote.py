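import itertools
import math

import numpy as np
import pytest

from autoclust import INDEX_DIRECTIONS, INDEX_NAMES, compute_index, vote_k
from autoclust.engines import MethodSpec, Partition, default_method
from autoclust.k_vote import _Geometry


def brute_pair_stats(X, labels):
    """Exhaustive enumeration of every sample pair: within/between counts,
    distance sums, extreme-distance sums and concordant/discordant pairs."""
    n = len(X)
    dists, within = [], []
    for i, j in itertools.combinations(range(n), 2):
        dists.append(float(np.linalg.norm(X[i] - X[j])))
        within.append(labels[i] == labels[j])
    dw = [d for d, w in zip(dists, within) if w]
    db = [d for d, w in zip(dists, within) if not w]
    s_plus = sum(1 for a in dw for b in db if a < b)
    s_minus = sum(1 for a in dw for b in db if a > b)
    N_W, N_B = len(dw), len(db)
    d_sorted = sorted(dists)
    return {
        "N_W": N_W,
        "N_B": N_B,
        "N_T": N_W + N_B,
        "S_W": sum(dw),
        "S_B": sum(db),
        "S_MIN": sum(d_sorted[:N_W]),
        "S_MAX": sum(d_sorted[-N_W:]) if N_W else 0.0,
        "s_plus": s_plus,
        "s_minus": s_minus,
    }


@pytest.fixture(scope="module")
def random_instances():
    rng = np.random.default_rng(17)
    cases = []
    for n in (6, 9, 12):
        for _ in range(3):
            X = rng.normal(size=(n, 3))
            labels = rng.integers(1, 4, size=n)
            while len(set(labels.tolist())) < 2:
                labels = rng.integers(1, 4, size=n)
            cases.append((X, labels))
    return cases


class TestPairCountOracle:
    def test_geometry_matches_enumeration(self, random_instances):
        for X, labels in random_instances:
            ref = brute_pair_stats(X, labels)
            geom = _Geometry(X, Partition(labels, 3))
            assert geom.N_W == ref["N_W"] and geom.N_B == ref["N_B"] and geom.N_T == ref["N_T"]
            assert geom.S_W == pytest.approx(ref["S_W"])
            assert geom.S_B == pytest.approx(ref["S_B"])
            s_plus, s_minus = geom.pair_counts()
            assert (s_plus, s_minus) == (ref["s_plus"], ref["s_minus"])

    def test_pair_based_indexes_match_formulas(self, random_instances):
        for X, labels in random_instances:
            ref = brute_pair_stats(X, labels)
            part = Partition(labels, 3)
            gamma = compute_index("gamma", X, part)
            if ref["s_plus"] + ref["s_minus"] > 0:
                assert gamma == pytest.approx(
                    (ref["s_plus"] - ref["s_minus"]) / (ref["s_plus"] + ref["s_minus"])
                )
            expected_tau = (ref["s_plus"] - ref["s_minus"]) / math.sqrt(
                ref["N_B"] * ref["N_W"] * ref["N_T"] * (ref["N_T"] - 1) / 2.0
            )
            assert compute_index("tau", X, part) == pytest.approx(expected_tau)
            assert compute_index("g_plus", X, part) == pytest.approx(
                2.0 * ref["s_minus"] / (ref["N_T"] * (ref["N_T"] - 1))
            )
            expected_c = (ref["S_W"] - ref["S_MIN"]) / (ref["S_MAX"] - ref["S_MIN"])
            assert compute_index("c_index", X, part) == pytest.approx(expected_c)
            assert compute_index("mcclain_rao", X, part) == pytest.approx(
                (ref["N_B"] / ref["N_W"]) * (ref["S_W"] / ref["S_B"])
            )


class TestComputeIndex:
    def test_silhouette_two_tight_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        part = Partition(np.array([1, 1, 2, 2]), 2)
        # a = 0.1, b ~ 10.05 -> s ~ 0.99
        assert compute_index("silhouette", X, part) == pytest.approx(0.99, abs=0.005)

    def test_calinski_harabasz_prefers_true_split(self, two_blobs):
        em, truth = two_blobs
        rng = np.random.default_rng(3)
        shuffled = rng.permutation(truth)
        good = compute_index("calinski_harabasz", em.values, Partition(truth, 2))
        bad = compute_index("calinski_harabasz", em.values, Partition(shuffled, 2))
        assert good > bad

    def test_c_index_zero_for_perfect_partition(self, two_blobs):
        # within-cluster pairs are exactly the N_W globally smallest distances
        em, truth = two_blobs
        assert compute_index("c_index", em.values, Partition(truth, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_cluster_abstains_not_raises(self):
        X = np.vstack([np.zeros((5, 2)), [[50.0, 50.0]]])
        part = Partition(np.array([1, 1, 1, 1, 1, 2]), 2)
        for name in INDEX_NAMES:
            value = compute_index(name, X, part)
            assert isinstance(value, float)  # NaN allowed, exceptions are not

    def test_unknown_index_rejected(self, two_blobs):
        em, truth = two_blobs
        with pytest.raises(ValueError):
            compute_index("gap_statistic", em.values, Partition(truth, 2))


class TestVoteK:
    def test_three_blobs_vote_three(self, three_blobs):
        em, truth = three_blobs
        table = vote_k(em.values, default_method("kmeans"), (2, 5), seed=0)
        assert table.top_estimate == 3
        assert sum(table.vote_counts.values()) == table.n_voting
        assert all(2 <= v <= 5 for v in table.index_votes.values() if v is not None)
        pct = sum(p for _, p in table.ranked_estimates)
        assert pct == pytest.approx(100.0)

    def test_two_point_masses_vote_two(self):
        X = np.vstack([np.tile([0.0, 0.0], (6, 1)), np.tile([30.0, 30.0], (6, 1))])
        table = vote_k(X, default_method("kmeans"), (2, 4), seed=1)
        assert table.top_estimate == 2

    def test_count_ties_break_to_larger_k(self):
        table = __import__("autoclust").k_vote.VoteTable(
            index_scores={}, index_votes={}, vote_counts={2: 3, 3: 3},
            ranked_estimates=sorted({2: 3, 3: 3}.items(), key=lambda kv: (-kv[1], -kv[0])),
        )
        table.ranked_estimates = [(k, 50.0) for k, _ in table.ranked_estimates]
        assert table.top_estimate == 3

    def test_index_own_tie_breaks_to_larger_k(self, three_blobs):
        em, _ = three_blobs
        table = vote_k(em.values, default_method("kmeans"), (2, 5), seed=0)
        # connectivity is 0 for every k that keeps neighbours together; its
        # vote must sit at the largest such k
        curve = table.index_scores["connectivity"]
        finite = {k: v for k, v in curve.items() if not math.isnan(v)}
        best = min(finite.values())
        assert table.index_votes["connectivity"] == max(k for k, v in finite.items() if v == best)

    def test_seeded_reproducibility(self, small_multiclass):
        X = small_multiclass.matrix.values
        t1 = vote_k(X, default_method("spectral"), (2, 4), seed=5)
        t2 = vote_k(X, default_method("spectral"), (2, 4), seed=5)
        assert t1.vote_counts == t2.vote_counts and t1.ranked_estimates == t2.ranked_estimates
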