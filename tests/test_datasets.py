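"""Synthetic data generation, coarse-graining and pool bookkeeping."""

import math

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import mtal
from mtal.datasets import KU_ACTIVITIES, _ku_maps_as_int
from mtal.exceptions import MissingMappingError


class TestGenerateFineGrained:
    def test_one_sample_per_class_under_uniform_proportions(self):
        X, fine = mtal.generate_fine_grained(18, 4, 18, separation=3.0, seed=0)
        assert X.shape == (18, 4)
        assert sorted(fine.tolist()) == list(range(18))

    def test_zero_separation_collapses_class_means(self):
        X, fine = mtal.generate_fine_grained(4000, 6, 2, separation=0.0, seed=3)
        gap = np.linalg.norm(X[fine == 0].mean(0) - X[fine == 1].mean(0))
        assert gap < 0.2  # class-conditional means coincide up to sampling noise

    def test_separated_classes_are_linearly_recoverable(self):
        # held-out fine-class accuracy of a multinomial classifier at separation 6
        X, fine = mtal.generate_fine_grained(3000, 16, 18, separation=6.0, seed=7)
        clf = LogisticRegression(max_iter=2000).fit(X[:1500], fine[:1500])
        assert (clf.predict(X[1500:]) == fine[1500:]).mean() >= 0.95

    def test_bit_reproducible_under_fixed_seed(self):
        a = mtal.generate_fine_grained(200, 5, 4, separation=2.0, seed=42)
        b = mtal.generate_fine_grained(200, 5, 4, separation=2.0, seed=42)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_proportions_counted_exactly(self):
        _, fine = mtal.generate_fine_grained(
            1000, 3, 3, separation=2.0, proportions=[0.5, 0.3, 0.2], seed=1
        )
        assert np.bincount(fine).tolist() == [500, 300, 200]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=0, n_features=3, n_fine=2, separation=1.0),
            dict(n=10, n_features=0, n_fine=2, separation=1.0),
            dict(n=10, n_features=3, n_fine=1, separation=1.0),
            dict(n=10, n_features=3, n_fine=2, separation=1.0, proportions=[0.9, 0.3]),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mtal.generate_fine_grained(**kwargs, seed=0)


class TestCoarseGrainTasks:
    def test_identity_map_returns_fine_labels(self):
        fine = np.array([0, 2, 1, 2, 0])
        out = mtal.coarse_grain_tasks(fine, [list(range(3))])
        assert (out[:, 0] == fine).all()

    def test_activity_style_maps_place_run_in_vigorous_categories(self):
        # "run" belongs to the exercise / vigorous / highly-stress-relieving classes
        run = KU_ACTIVITIES.index("run")
        out = mtal.coarse_grain_tasks(np.array([run]), _ku_maps_as_int())
        assert out.tolist() == [[2, 2, 2]]

    def test_relabeled_identical_maps_give_perfect_association(self, rng):
        fine = rng.integers(0, 3, size=300)
        relabel = [2, 0, 1]
        labels = mtal.coarse_grain_tasks(fine, [[0, 1, 2], relabel])
        # brute-force contingency: every class of one column maps to exactly one
        # class of the other
        table = np.zeros((3, 3), dtype=int)
        for a, b in zip(labels[:, 0], labels[:, 1]):
            table[a, b] += 1
        assert ((table > 0).sum(axis=1) == 1).all()
        assoc = mtal.pairwise_association(labels, method="cramers_v")
        assert assoc[0, 1] == pytest.approx(1.0)

    def test_unmapped_fine_class_raises_with_class_named(self):
        with pytest.raises(MissingMappingError, match="3"):
            mtal.coarse_grain_tasks(np.array([0, 3]), [{0: 0, 1: 1, 2: 1}])

    def test_deterministic_and_idempotent_under_identity(self, rng):
        fine = rng.integers(0, 5, size=100)
        maps = [[0, 0, 1, 1, 2], [0, 1, 0, 1, 0]]
        once = mtal.coarse_grain_tasks(fine, maps)
        again = mtal.coarse_grain_tasks(fine, maps)
        assert (once == again).all()
        for i in range(once.shape[1]):
            c = once[:, i].max() + 1
            redo = mtal.coarse_grain_tasks(once[:, i], [list(range(c))])
            assert (redo[:, 0] == once[:, i]).all()


class TestAssembleAndSeed:
    def test_dataset_invariants_hold(self, ku_small):
        ku_small.validate()  # raises on violation
        assert ku_small.n_tasks == 3
        assert all(t.n_classes == 3 for t in ku_small.tasks)

    def test_seed_split_sizes(self, ku_full):
        pool = mtal.split_seed(ku_full, 3, seed=5)
        assert pool.n_labeled == 3
        assert pool.n_unlabeled == len(ku_full.train_indices) - 3
        pool.validate()

    def test_seed_split_deterministic(self, ku_small):
        a = mtal.split_seed(ku_small, 3, seed=9)
        b = mtal.split_seed(ku_small, 3, seed=9)
        assert (a.labeled == b.labeled).all() and (a.unlabeled == b.unlabeled).all()

    def test_seed_size_must_be_below_train_size(self, ku_small):
        with pytest.raises(ValueError):
            mtal.split_seed(ku_small, len(ku_small.train_indices), seed=0)

    def test_tiny_seed_misses_classes_at_the_analytic_rate(self, ku_full):
        # P(3 uniform draws without replacement cover all 3 classes of a task)
        # by inclusion-exclusion over the actual train-pool class counts
        task = 1
        counts = np.bincount(ku_full.labels[ku_full.train_indices, task], minlength=3)
        n = counts.sum()
        def p_avoid(subset):
            keep = n - sum(counts[list(subset)])
            return math.comb(keep, 3) / math.comb(n, 3)
        p_miss = (
            sum(p_avoid({c}) for c in range(3))
            - sum(p_avoid({a, b}) for a in range(3) for b in range(a + 1, 3))
        )
        misses = 0
        repeats = 1000
        for s in range(repeats):
            pool = mtal.split_seed(ku_full, 3, seed=s)
            misses += np.unique(ku_full.labels[pool.labeled, task]).size < 3
        rate = misses / repeats
        sigma = math.sqrt(p_miss * (1 - p_miss) / repeats)
        assert rate > 0
        assert abs(rate - p_miss) < 4 * sigma

    def test_pool_conservation_under_moves(self, ku_small, rng):
        pool = mtal.split_seed(ku_small, 3, seed=1)
        total = pool.n_train
        for _ in range(5):
            chosen = rng.choice(pool.unlabeled, size=7, replace=False)
            pool.move_to_labeled(chosen)
            pool.validate()
            assert pool.n_labeled + pool.n_unlabeled == total


class TestAssociationMonotonicity:
    def test_association_grows_with_map_congruence(self, rng):
        fine = rng.integers(0, 6, size=2000)
        base = [0, 0, 1, 1, 2, 2]
        scrambled = [0, 1, 2, 0, 1, 2]   # cuts across the base grouping
        half = [0, 0, 1, 2, 2, 1]        # agrees with base on 4 of 6 classes
        assocs = []
        for second in (scrambled, half, base):
            labels = mtal.coarse_grain_tasks(fine, [base, second])
            assocs.append(mtal.pairwise_association(labels, method="cramers_v")[0, 1])
        assert assocs[0] < assocs[1] < assocs[2]


class TestDiskRoundTrip:
    def test_csv_json_round_trip(self, tmp_path, ku_small):
        prefix = tmp_path / "bench"
        csv_path, json_path = mtal.save_dataset(ku_small, prefix)
        assert csv_path.exists() and json_path.exists()
        back = mtal.load_dataset(prefix)
        assert np.allclose(back.features, ku_small.features)
        assert (back.labels == ku_small.labels).all()
        assert (back.train_indices == ku_small.train_indices).all()
        assert [t.name for t in back.tasks] == [t.name for t in ku_small.tasks]
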