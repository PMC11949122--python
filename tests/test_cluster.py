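import numpy as np
import pytest
from scipy.spatial.distance import squareform

from cachetraj import (DistanceMatrix, adjusted_rand_index, k_medoids,
                       select_k, silhouette)
from helpers import best_medoids_exhaustive


def _dm(dense):
    dense = np.asarray(dense, float)
    return DistanceMatrix([f"P{i}" for i in range(len(dense))],
                          squareform(dense, checks=False), "dtw_normalized")


def _block_matrix(sizes, within=0.05, between=1.0, jitter=0.0, seed=0):
    """Well-separated block-structured distances with optional jitter."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    dense = np.where(labels[:, None] == labels[None, :], within, between)
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, jitter, size=(n, n))
        dense = dense + (noise + noise.T) / 2
    np.fill_diagonal(dense, 0.0)
    return _dm(dense), labels


class TestKMedoids:
    def test_two_pair_blocks_recovered_with_zero_cost(self):
        dense = np.ones((4, 4))
        dense[0, 1] = dense[1, 0] = dense[2, 3] = dense[3, 2] = 0.0
        np.fill_diagonal(dense, 0.0)
        sol = k_medoids(_dm(dense), 2)
        assert sol.total_cost == 0.0
        assert sol.labels[0] == sol.labels[1] != sol.labels[2] == sol.labels[3]
        med, cost = best_medoids_exhaustive(dense, 2)
        assert sol.total_cost == cost

    def test_degenerate_all_zero_distances(self):
        sol = k_medoids(_dm(np.zeros((5, 5))), 2)
        assert sol.total_cost == 0.0
        assert len(set(sol.labels)) >= 1  # deterministic labeling

    def test_three_blocks_recovered_exactly(self):
        dm, truth = _block_matrix([10, 10, 10], jitter=0.02, seed=3)
        sol = k_medoids(dm, 3)
        assert adjusted_rand_index(sol.labels, truth) == 1.0
        med, cost = best_medoids_exhaustive(dm.values, 3)
        assert sol.total_cost == pytest.approx(cost)

    def test_near_exhaustive_optimum_on_random_matrices(self):
        # PAM guarantees a single-swap local optimum, not the global one;
        # on tiny unstructured problems it should still land close to it
        rng = np.random.default_rng(11)
        for _ in range(5):
            dense = rng.uniform(0.1, 1, size=(9, 9))
            dense = (dense + dense.T) / 2
            np.fill_diagonal(dense, 0)
            sol = k_medoids(_dm(dense), 3)
            _, best_cost = best_medoids_exhaustive(dense, 3)
            assert best_cost - 1e-12 <= sol.total_cost <= 1.15 * best_cost

    def test_no_single_swap_improves(self):
        rng = np.random.default_rng(5)
        dense = rng.uniform(0.1, 1, size=(12, 12))
        dense = (dense + dense.T) / 2
        np.fill_diagonal(dense, 0)
        sol = k_medoids(_dm(dense), 3)
        base = sol.total_cost
        for mi in range(3):
            for h in range(12):
                if h in sol.medoids:
                    continue
                cand = sol.medoids.copy()
                cand[mi] = h
                cost = dense[cand].min(axis=0).sum()
                assert cost >= base - 1e-9

    def test_medoid_membership_invariant(self):
        dm, _ = _block_matrix([7, 8], jitter=0.03, seed=1)
        sol = k_medoids(dm, 2)
        for pos, m in enumerate(sol.medoids):
            assert sol.labels[m] == pos + 1

    @pytest.mark.parametrize("k", [1, 5, 6])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            k_medoids(_dm(np.zeros((5, 5))), k)

    def test_deterministic(self):
        dm, _ = _block_matrix([8, 9, 7], jitter=0.05, seed=9)
        a = k_medoids(dm, 3)
        b = k_medoids(dm, 3)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.medoids, b.medoids)


class TestSilhouette:
    def test_perfect_two_block_silhouette_is_one(self):
        dense = np.ones((4, 4))
        dense[0, 1] = dense[1, 0] = dense[2, 3] = dense[3, 2] = 0.0
        np.fill_diagonal(dense, 0.0)
        widths, mean = silhouette(_dm(dense), [1, 1, 2, 2])
        assert np.allclose(widths, 1.0)
        assert mean == 1.0

    def test_swapped_labels_give_negative_silhouette(self):
        dense = np.ones((4, 4))
        dense[0, 1] = dense[1, 0] = dense[2, 3] = dense[3, 2] = 0.0
        np.fill_diagonal(dense, 0.0)
        # a(i) = 1 within the crossed cluster; b(i) = mean(0, 1) = 0.5 to the
        # other crossed cluster, so s(i) = (0.5 - 1)/1 = -0.5 for every point
        _, mean = silhouette(_dm(dense), [1, 2, 1, 2])
        assert mean == -0.5

    def test_singleton_contributes_zero(self):
        dm, _ = _block_matrix([5, 1], jitter=0.0)
        widths, _ = silhouette(dm, [1] * 5 + [2])
        assert widths[-1] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(_dm(np.zeros((3, 3))), [1, 1, 1])


class TestSelectK:
    @pytest.mark.parametrize("sizes,expected_k", [([12, 11, 10], 3),
                                                  ([15, 14], 2)])
    def test_recovers_block_count(self, sizes, expected_k):
        dm, _ = _block_matrix(sizes, jitter=0.02, seed=2)
        sol = select_k(dm, 2, 8)
        assert sol.k == expected_k
        assert set(sol.sil_trace) == set(range(2, 9))

    def test_trace_is_consistent_with_choice(self):
        dm, _ = _block_matrix([10, 10, 10], jitter=0.02, seed=4)
        sol = select_k(dm, 2, 6)
        assert sol.avg_silhouette == max(sol.sil_trace.values())


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        assert adjusted_rand_index([1, 1, 2, 2, 3], [1, 1, 2, 2, 3]) == 1.0

    def test_crossed_pairs_value(self):
        # contingency table of all ones: ARI = -0.5 by the pair-counting formula
        assert adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_permutation_invariance(self):
        a = [1, 1, 2, 2, 3, 3]
        b = [3, 3, 1, 1, 2, 2]
        assert adjusted_rand_index(a, b) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    def test_works_with_string_labels(self):
        assert adjusted_rand_index(["a", "a", "b"], [1, 1, 2]) == 1.0
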