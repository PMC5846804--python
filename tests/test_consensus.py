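import itertools

import numpy as np
import pytest

from conncluster import (
    coassignment,
    consensus_matrix,
    consensus_pipeline,
    expected_coassignment,
    louvain_communities,
    modularity_matrix,
)
from conncluster.errors import ContractError
from conncluster.toymodel import ToySpec, simulate


def all_partitions(n):
    """Every set partition of n items as a label list (restricted growth)."""
    if n == 1:
        yield [0]
        return
    for p in all_partitions(n - 1):
        for c in range(max(p) + 2):
            yield p + [c]


def exhaustive_best_q(B):
    best = -np.inf
    best_lab = None
    for p in all_partitions(B.shape[0]):
        lab = np.array(p)
        same = lab[:, None] == lab[None, :]
        np.fill_diagonal(same, False)
        q = B[same].sum()
        if q > best:
            best, best_lab = q, lab
    return best, best_lab


class TestCoassignment:
    def test_two_pairs(self):
        M = coassignment(np.array([1, 1, 2, 2]))
        expected = np.array([[1, 1, 0, 0], [1, 1, 0, 0],
                             [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float)
        np.testing.assert_array_equal(M, expected)

    def test_single_cluster_all_ones(self):
        np.testing.assert_array_equal(coassignment(np.ones(4, dtype=int)),
                                      np.ones((4, 4)))

    def test_all_distinct_is_identity(self):
        np.testing.assert_array_equal(coassignment(np.arange(1, 5)), np.eye(4))


class TestConsensusMatrix:
    def test_hand_counted_two_partitions(self):
        C = consensus_matrix([np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2])])
        v = C.values
        assert v[0, 1] == v[0, 2] == v[1, 3] == v[2, 3] == 0.5
        assert v[0, 3] == v[1, 2] == 0.0
        assert np.all(np.diag(v) == 1.0)

    def test_identical_partitions_give_binary(self):
        lab = np.array([1, 2, 1, 2, 1])
        C = consensus_matrix([lab] * 7)
        assert set(np.unique(C.values)) <= {0.0, 1.0}

    def test_entries_on_rational_grid(self, toy_small):
        dstack, _ = toy_small
        res = consensus_pipeline(dstack, k_values=[2, 3], seed=0, restarts=2,
                                 louvain_runs=5)
        C = res.consensus
        scaled = C.values * C.n_partitions
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)

    def test_mixed_m_rejected(self):
        with pytest.raises(ContractError):
            consensus_matrix([np.array([1, 2]), np.array([1, 2, 1])])

    def test_toy_consensus_has_planted_blocks(self, toy_default):
        """At fixed k=10 the consensus matrix is visibly block-structured."""
        from conncluster.layercluster import partition_ensemble

        dstack, truth = toy_default
        parts = partition_ensemble(dstack, [10], seed=0, restarts=3)
        C = consensus_matrix(parts).values
        same = truth.labels[:, None] == truth.labels[None, :]
        off = ~np.eye(len(same), dtype=bool)
        within = C[same & off].mean()
        between = C[~same].mean()
        assert within > 1.5 * between


class TestExpectedCoassignment:
    def test_enumeration_oracle_two_pairs(self):
        """All 4! label permutations of sizes {2,2}: off-diagonal P = 1/3."""
        lab = np.array([1, 1, 2, 2])
        acc = np.zeros((4, 4))
        for perm in itertools.permutations(lab):
            acc += coassignment(np.array(perm))
        oracle = acc / 24
        P = expected_coassignment([lab], mode="analytic")
        np.testing.assert_allclose(P, oracle, atol=1e-12)
        assert P[0, 1] == pytest.approx(1 / 3)

    def test_single_cluster_gives_all_ones(self):
        P = expected_coassignment([np.ones(5, dtype=int)])
        np.testing.assert_array_equal(P, np.ones((5, 5)))

    def test_four_blocks_closed_form(self):
        lab = np.repeat(np.arange(1, 5), 25)
        P = expected_coassignment([lab], mode="analytic")
        assert P[0, 99] == pytest.approx(4 * 25 * 24 / (100 * 99), abs=1e-15)

    def test_permutation_mode_converges_to_analytic(self):
        lab = np.repeat(np.arange(1, 5), 25)
        Pa = expected_coassignment([lab], mode="analytic")
        Pp = expected_coassignment([lab], mode="permutation", n_perm=10_000,
                                   seed=3)
        assert np.abs(Pa - Pp).max() < 4 / np.sqrt(10_000)

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            expected_coassignment([np.array([1, 2, 1])], mode="permutation",
                                  n_perm=0)


class TestModularityMatrix:
    def test_null_case(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        np.testing.assert_array_equal(modularity_matrix(C, C), np.zeros((3, 3)))

    def test_two_block_arithmetic(self):
        lab = np.array([1, 1, 2, 2])
        C = coassignment(lab)
        P = expected_coassignment([lab], mode="analytic")
        B = modularity_matrix(C, P)
        assert B[0, 1] == pytest.approx(2 / 3)
        assert B[0, 2] == pytest.approx(-1 / 3)
        assert np.all(np.diag(B) == 0.0)

    def test_sum_identity_with_analytic_null(self, toy_small):
        dstack, _ = toy_small
        res = consensus_pipeline(dstack, k_values=[2, 3], seed=1, restarts=2,
                                 louvain_runs=5)
        C, P, B = res.consensus.values, res.P, res.B
        m = C.shape[0]
        pbar = P[0, 1]
        off = ~np.eye(m, dtype=bool)
        assert B[off].sum() == pytest.approx(C[off].sum() - m * (m - 1) * pbar,
                                             abs=1e-9)

    def test_toy_sign_pattern(self, toy_default):
        dstack, truth = toy_default
        res = consensus_pipeline(dstack, k_values=range(2, 12), seed=0,
                                 restarts=2, louvain_runs=5)
        same = truth.labels[:, None] == truth.labels[None, :]
        off = ~np.eye(len(same), dtype=bool)
        assert res.B[same & off].mean() > 0
        assert res.B[~same].mean() < 0

    def test_shape_mismatch(self):
        with pytest.raises(ContractError):
            modularity_matrix(np.eye(3), np.eye(4))


class TestLouvain:
    def test_two_block_optimum_confirmed_exhaustively(self):
        lab = np.array([1, 1, 2, 2])
        B = modularity_matrix(coassignment(lab),
                              expected_coassignment([lab]))
        res = louvain_communities(B, runs=10, seed=0, norm=1.0)
        q_best, lab_best = exhaustive_best_q(B)
        assert res.modularity_value == pytest.approx(q_best)
        assert res.n_communities == 2
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_zero_matrix_single_community(self):
        res = louvain_communities(np.zeros((5, 5)), runs=3, seed=0)
        assert res.n_communities == 1
        assert res.modularity_value == 0.0

    def test_never_below_zero_when_positive_merge_exists(self, rng):
        for t in range(20):
            A = rng.uniform(-0.5, 0.5, (6, 6))
            B = (A + A.T) / 2
            np.fill_diagonal(B, 0.0)
            res = louvain_communities(B, runs=5, seed=t, norm=1.0)
            if np.any(B[~np.eye(6, dtype=bool)] > 0):
                assert res.modularity_value >= 0.0

    def test_matches_exhaustive_on_small_instances(self, rng):
        hits = 0
        for t in range(30):
            m = int(rng.integers(4, 8))
            A = rng.uniform(-0.5, 0.5, (m, m))
            B = (A + A.T) / 2
            np.fill_diagonal(B, 0.0)
            res = louvain_communities(B, runs=20, seed=t, norm=1.0)
            q_best, _ = exhaustive_best_q(B)
            hits += abs(res.modularity_value - q_best) < 1e-9
        assert hits >= int(0.95 * 30)

    def test_determinism(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(-0.5, 0.5, (10, 10))
        B = (A + A.T) / 2
        np.fill_diagonal(B, 0.0)
        r1 = louvain_communities(B, runs=5, seed=9)
        r2 = louvain_communities(B, runs=5, seed=9)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.modularity_value == r2.modularity_value


class TestPipeline:
    def test_recovers_planted_groups(self, toy_small):
        dstack, truth = toy_small
        res = consensus_pipeline(dstack, k_values=[2, 3, 4], seed=0,
                                 restarts=3, louvain_runs=10)
        coms = res.communities.labels
        assert len(set(coms[:6])) == 1 and len(set(coms[6:])) == 1
        assert coms[0] != coms[6]

    def test_smallest_valid_input(self):
        layers = np.array([[[0, 0.5], [0.5, 0]], [[0, 0.4], [0.4, 0]]])
        from conncluster.distance import NodalDistanceStack

        res = consensus_pipeline(NodalDistanceStack(layers), k_values=[2],
                                 seed=0, restarts=2, louvain_runs=3)
        assert res.consensus.values.shape == (2, 2)
        assert len(res.communities.labels) == 2

    def test_rerun_bit_identical(self, toy_small):
        dstack, _ = toy_small
        r1 = consensus_pipeline(dstack, k_values=[2, 3], seed=4, restarts=2,
                                louvain_runs=5)
        r2 = consensus_pipeline(dstack, k_values=[2, 3], seed=4, restarts=2,
                                louvain_runs=5)
        np.testing.assert_array_equal(r1.consensus.values, r2.consensus.values)
        np.testing.assert_array_equal(r1.communities.labels,
                                      r2.communities.labels)
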