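import numpy as np
import pytest

from mircausal.evaluation import (
    EvaluationError,
    SplitError,
    auroc,
    evaluate_groups,
    mask_positives,
    rank_sum_test,
    split_folds,
    split_independent,
)
from mircausal.types import AssociationMatrix, ScoreMatrix

from oracles import auroc_pair_counting


def _cells(n):
    return [(i, 0) for i in range(n)]


class TestSplits:
    def test_one_fifth_of_ten(self):
        train, test = split_independent(_cells(10), 0.2, seed=0)
        assert len(test) == 2 and len(train) == 8
        assert set(train) | set(test) == set(_cells(10))
        assert not set(train) & set(test)

    def test_same_seed_reproduces_split(self):
        assert split_independent(_cells(10), 0.2, seed=5) == split_independent(
            _cells(10), 0.2, seed=5
        )

    def test_half_of_five_rounds_to_two_test(self):
        train, test = split_independent(_cells(5), 0.5, seed=1)
        assert sorted((len(train), len(test))) == [2, 3]
        assert len(test) == round(0.5 * 5)

    def test_too_few_positives_rejected(self):
        with pytest.raises(SplitError):
            split_independent(_cells(1), 0.2, seed=0)

    def test_ten_folds_of_ten_positives(self):
        folds = split_folds(_cells(10), 10, seed=0)
        assert sorted(np.bincount(folds).tolist()) == [1] * 10

    def test_eleven_positives_ten_folds(self):
        folds = split_folds(_cells(11), 10, seed=0)
        sizes = sorted(np.bincount(folds, minlength=10).tolist())
        assert sizes == [1] * 9 + [2]

    def test_fold_sizes_balanced_for_any_seed(self):
        for seed in range(5):
            sizes = np.bincount(split_folds(_cells(23), 5, seed=seed), minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_more_folds_than_positives_rejected(self):
        with pytest.raises(SplitError):
            split_folds(_cells(5), 10, seed=0)


class TestMasking:
    @staticmethod
    def _md(values):
        values = np.array(values, dtype=float)
        return AssociationMatrix(
            values,
            tuple(f"m{i}" for i in range(values.shape[0])),
            tuple(f"d{j}" for j in range(values.shape[1])),
        )

    def test_masking_only_positive_gives_zero_matrix(self):
        md = self._md([[0, 1], [0, 0]])
        masked = mask_positives(md, [(0, 1)])
        assert masked.values.sum() == 0
        assert md.values.sum() == 1  # original untouched

    def test_masking_nothing_is_identity(self):
        md = self._md([[1, 0], [0, 1]])
        assert (mask_positives(md, []).values == md.values).all()

    def test_masking_zero_cell_rejected(self):
        md = self._md([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            mask_positives(md, [(0, 1)])
        # double masking hits the same consistency guard
        with pytest.raises(ValueError):
            mask_positives(md, [(0, 0), (0, 0)])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0

    def test_tied_example(self):
        assert auroc([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_random_scores_near_half(self, rng):
        scores = rng.random(2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        assert abs(auroc(scores, labels) - 0.5) < 0.05

    def test_degenerate_labels_rejected(self):
        with pytest.raises(EvaluationError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        """Implementation equals brute-force pair counting, with ties."""
        for _ in range(100):
            n = int(rng.integers(2, 201))
            scores = rng.choice(np.linspace(0, 1, 20), size=n)
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            assert auroc(scores, labels) == pytest.approx(
                auroc_pair_counting(scores, labels), abs=1e-12
            )


class TestRankSum:
    def test_identical_groups_not_significant(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_fully_separated_small_groups_exact(self):
        u, p = rank_sum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        # exact enumeration: one-sided 1/C(6,3) = 0.05, two-sided 0.1
        assert p == pytest.approx(0.1)

    def test_two_sided_p_symmetric_under_swap(self, rng):
        a, b = rng.normal(size=10), rng.normal(loc=0.5, size=12)
        _, p_ab = rank_sum_test(a, b)
        _, p_ba = rank_sum_test(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_exact_and_asymptotic_agree_at_boundary(self, rng):
        """At n=8 per group the two branches differ by < 10% relative p."""
        from scipy import stats

        compared = 0
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(loc=0.3, size=8)
            _, p_pkg = rank_sum_test(a, b)  # exact branch (no ties)
            p_asym = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            if p_pkg < 0.05:
                continue  # deep tail: the normal approximation degrades there
            assert abs(p_pkg - p_asym) / p_pkg < 0.1
            compared += 1
        assert compared >= 10

    def test_empty_group_rejected(self):
        with pytest.raises(EvaluationError):
            rank_sum_test([], [1.0])


class TestEvaluateGroups:
    @staticmethod
    def _setup(score_values, labels):
        nm, nd = score_values.shape
        scores = ScoreMatrix(
            score_values,
            tuple(f"m{i}" for i in range(nm)),
            tuple(f"d{j}" for j in range(nd)),
        )
        return scores, labels

    def test_planted_ordering_gives_perfect_aurocs(self):
        values = np.array([[0.9, 0.8], [0.5, 0.4], [0.1, 0.0]])
        labels = np.array(
            [["causal", "causal"], ["non-causal", "non-causal"], ["none", "none"]],
            dtype=object,
        )
        scores, labels = self._setup(values, labels)
        report = evaluate_groups(scores, labels)
        assert report.causal_vs_none_auroc == 1.0
        assert report.causal_vs_noncausal_auroc == 1.0
        assert len(report.rank_sum) == 3

    def test_shuffled_labels_give_chance_aurocs(self, rng):
        values = rng.random((40, 30))
        labels = rng.choice(["causal", "non-causal", "none"], size=(40, 30)).astype(object)
        scores, labels = self._setup(values, labels)
        report = evaluate_groups(scores, labels)
        assert abs(report.causal_vs_none_auroc - 0.5) < 0.06
        assert abs(report.causal_vs_noncausal_auroc - 0.5) < 0.06

    def test_group_sizes_sum_to_grid(self, rng):
        values = rng.random((6, 5))
        labels = rng.choice(["causal", "non-causal", "none"], size=(6, 5)).astype(object)
        scores, labels = self._setup(values, labels)
        report = evaluate_groups(scores, labels)
        assert sum(report.group_sizes.values()) == 30

    def test_empty_group_reported_as_absent(self):
        values = np.array([[0.9, 0.1]])
        labels = np.array([["causal", "none"]], dtype=object)
        scores, labels = self._setup(values, labels)
        report = evaluate_groups(scores, labels)
        assert report.causal_vs_noncausal_auroc is None
        assert {(c.group_a, c.group_b) for c in report.rank_sum} == {("causal", "none")}
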