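"""Query strategies: reference-task rule, selectors, brute-force oracles."""

import numpy as np
import pytest

import mtal
from conftest import random_prob_rows


def make_pool(m, offset=0):
    unlabeled = np.arange(offset, offset + m)
    return mtal.PoolState(labeled=np.array([offset + m]), unlabeled=unlabeled, n_seed=1)


def brute_top_b(scores, unlabeled, b):
    """Independent oracle: stable sort by (-score, index)."""
    order = sorted(range(len(scores)), key=lambda r: (-scores[r], unlabeled[r]))
    return [unlabeled[r] for r in order[:b]]


def brute_rank_sums(scores):
    """Independent oracle: fractional ranks per column, 1 = highest score."""
    m, T = scores.shape
    sums = np.zeros(m)
    for t in range(T):
        col = scores[:, t]
        for r in range(m):
            higher = (col > col[r]).sum()
            ties = (col == col[r]).sum()
            sums[r] += higher + (ties + 1) / 2
    return sums


class TestCombinedCorrelation:
    def test_high_congruence_worked_example(self):
        R = np.array([[0, 0.8, 0.75], [0.8, 0, 0.927], [0.75, 0.927, 0]])
        combined = mtal.combined_correlation(matrix=R)
        assert np.round(combined, 2).tolist() == [1.55, 1.73, 1.68]
        assert mtal.reference_task(matrix=R) == 1

    def test_low_congruence_worked_example(self):
        R = np.array([[0, 0.15, 0.4], [0.15, 0, 0.26], [0.4, 0.26, 0]])
        combined = mtal.combined_correlation(matrix=R)
        assert np.round(combined, 2).tolist() == [0.55, 0.41, 0.66]
        assert mtal.reference_task(matrix=R) == 2

    def test_identical_columns_tie_broken_to_lowest_index(self, rng):
        col = rng.integers(0, 3, 200)
        labels = np.column_stack([col, col])
        combined = mtal.combined_correlation(labels)
        assert combined == pytest.approx([1.0, 1.0])
        assert mtal.reference_task(labels) == 0

    def test_constant_column_contributes_zero_with_warning(self, rng):
        labels = np.column_stack([np.zeros(50, dtype=int), rng.integers(0, 2, 50), rng.integers(0, 2, 50)])
        with pytest.warns(UserWarning, match="constant"):
            combined = mtal.combined_correlation(labels)
        assert combined[0] == 0.0

    def test_matches_dataset_level_statistics(self, ku_small):
        # combined correlation from labels agrees with the pairwise matrix route
        R = mtal.pairwise_association(ku_small.labels)
        assert np.allclose(mtal.combined_correlation(ku_small.labels), mtal.combined_correlation(matrix=R))


class TestOneSided:
    def test_top_two_selection(self):
        pool = make_pool(3)
        U = mtal.UncertaintyMatrix(np.array([[0.1], [0.9], [0.5]]), "least_confidence")
        batch = mtal.select_one_sided(U, 0, pool, 2)
        assert set(batch.indices.tolist()) == {1, 2}

    def test_all_equal_scores_take_lowest_indices(self):
        pool = make_pool(5)
        U = mtal.UncertaintyMatrix(np.full((5, 2), 0.3), "least_confidence")
        batch = mtal.select_one_sided(U, 1, pool, 2)
        assert batch.indices.tolist() == [0, 1]

    def test_matches_brute_force_sort(self, rng):
        pool = make_pool(50, offset=100)
        scores = rng.random((50, 3))
        U = mtal.UncertaintyMatrix(scores, "entropy")
        batch = mtal.select_one_sided(U, 1, pool, 10)
        assert batch.indices.tolist() == brute_top_b(scores[:, 1], pool.unlabeled, 10)

    def test_oversized_batch_truncates_with_warning(self):
        pool = make_pool(4)
        U = mtal.UncertaintyMatrix(np.random.default_rng(0).random((4, 1)), "entropy")
        with pytest.warns(UserWarning, match="truncat"):
            batch = mtal.select_one_sided(U, 0, pool, 9)
        assert len(batch) == 4


class TestAlternating:
    def test_round_robin_reference(self, rng):
        pool = make_pool(6)
        scores = rng.random((6, 3))
        U = mtal.UncertaintyMatrix(scores, "least_confidence")
        for k in (0, 1, 2, 3):
            batch = mtal.select_alternating(U, k, pool, 2)
            expected = mtal.select_one_sided(U, k % 3, pool, 2)
            assert batch.indices.tolist() == expected.indices.tolist()

    def test_single_task_degenerates_to_one_sided(self, rng):
        pool = make_pool(8)
        U = mtal.UncertaintyMatrix(rng.random((8, 1)), "entropy")
        for k in range(4):
            batch = mtal.select_alternating(U, k, pool, 3)
            assert batch.indices.tolist() == mtal.select_one_sided(U, 0, pool, 3).indices.tolist()

    def test_each_task_referenced_equally_often(self):
        T = 3
        refs = [k % T for k in range(3 * T)]
        assert all(refs.count(t) == 3 for t in range(T))


class TestRankCombination:
    def test_hand_computed_rank_sums(self):
        pool = make_pool(3)
        ent = np.array([[0.2, 0.8], [0.9, 0.7], [0.5, 0.1]])
        U = mtal.UncertaintyMatrix(ent, "entropy")
        assert mtal.rank_sums(ent).tolist() == [4.0, 3.0, 5.0]
        batch = mtal.select_rank_combination(U, pool, 1)
        assert batch.indices.tolist() == [1]
        assert batch.provenance[0]["rank_sum"] == 3.0

    def test_single_task_equals_one_sided_entropy(self, rng):
        pool = make_pool(20)
        U = mtal.UncertaintyMatrix(rng.random((20, 1)), "entropy")
        rc = mtal.select_rank_combination(U, pool, 5)
        os = mtal.select_one_sided(U, 0, pool, 5)
        assert rc.indices.tolist() == os.indices.tolist()

    def test_matches_brute_force_rank_sum_sort(self, rng):
        pool = make_pool(40, offset=7)
        scores = rng.random((40, 3))
        U = mtal.UncertaintyMatrix(scores, "entropy")
        batch = mtal.select_rank_combination(U, pool, 8)
        sums = brute_rank_sums(scores)
        expected = brute_top_b(-sums, pool.unlabeled, 8)
        assert batch.indices.tolist() == expected

    def test_invariant_to_monotone_transform_of_a_column(self, rng):
        pool = make_pool(30)
        scores = rng.random((30, 3))
        warped = scores.copy()
        warped[:, 1] = np.exp(3 * warped[:, 1])  # strictly increasing transform
        a = mtal.select_rank_combination(mtal.UncertaintyMatrix(scores, "entropy"), pool, 6)
        b = mtal.select_rank_combination(mtal.UncertaintyMatrix(warped, "entropy"), pool, 6)
        assert a.indices.tolist() == b.indices.tolist()


class TestRandomBaseline:
    def test_exhaustion_returns_whole_pool(self):
        pool = make_pool(5)
        batch = mtal.select_random(pool, 5, seed=0)
        assert sorted(batch.indices.tolist()) == pool.unlabeled.tolist()

    def test_deterministic_under_seed(self):
        pool = make_pool(30)
        a = mtal.select_random(pool, 6, seed=42)
        b = mtal.select_random(pool, 6, seed=42)
        assert a.indices.tolist() == b.indices.tolist()

    def test_selection_frequencies_uniform(self):
        pool = make_pool(10)
        repeats = 10_000
        counts = np.zeros(10)
        for s in range(repeats):
            counts[mtal.select_random(pool, 1, seed=s).indices[0]] += 1
        sigma = np.sqrt(repeats * 0.1 * 0.9)
        assert (np.abs(counts - repeats / 10) < 3.5 * sigma).all()


class TestBatchHygiene:
    def test_no_strategy_selects_labeled_or_duplicate_indices(self, rng):
        pool = mtal.PoolState(labeled=np.arange(5), unlabeled=np.arange(5, 45), n_seed=5)
        U = mtal.UncertaintyMatrix(rng.random((40, 3)), "entropy")
        batches = [
            mtal.select_one_sided(U, 0, pool, 12),
            mtal.select_alternating(U, 2, pool, 12),
            mtal.select_rank_combination(U, pool, 12),
            mtal.select_random(pool, 12, seed=3),
        ]
        for batch in batches:
            idx = batch.indices
            assert len(np.unique(idx)) == len(idx) == 12
            assert np.isin(idx, pool.unlabeled).all()
            assert not np.isin(idx, pool.labeled).any()
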