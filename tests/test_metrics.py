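"""Clustering-agreement scores, ROC/AUC, confusion counts, and K-fold CV."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score, roc_auc_score

from schictype.metrics import (
    CVConfig,
    ConfusionCounts,
    accuracy,
    ari,
    confusion,
    contingency,
    entropy,
    evaluate,
    kfold_cv,
    kfold_indices,
    macro_auc,
    mutual_information,
    nmi,
    roc_auc,
    tpr_fpr,
)


def ari_pair_oracle(a, b):
    """Exhaustive pair co-assignment counting (Rand index, then adjustment)."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            n11 += 1
        elif not same_a and not same_b:
            n00 += 1
        elif same_a:
            n10 += 1
        else:
            n01 += 1
    total = n * (n - 1) / 2
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = ((n11 + n10) + (n11 + n01)) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


class TestContingency:
    def test_diagonal_and_crossed_tables(self):
        t = contingency([0, 0, 1, 1], [0, 0, 1, 1])
        np.testing.assert_array_equal(t.counts, [[2, 0], [0, 2]])
        t = contingency([0, 0, 1, 1], [0, 1, 0, 1])
        np.testing.assert_array_equal(t.counts, np.ones((2, 2)))

    def test_marginals_match_class_counts(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, size=50)
        b = rng.integers(0, 3, size=50)
        t = contingency(a, b)
        for lab, count in zip(t.row_labels, t.row_marginal):
            assert count == np.sum(a == lab)
        for lab, count in zip(t.col_labels, t.col_marginal):
            assert count == np.sum(b == lab)
        assert t.n == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contingency([0, 1], [0])


class TestInformation:
    def test_independent_partitions_have_zero_mi(self):
        t = contingency([0, 0, 1, 1], [0, 1, 0, 1])
        assert mutual_information(t) == pytest.approx(0.0, abs=1e-15)

    def test_identical_two_block_partition_gives_log2(self):
        t = contingency([0, 0, 1, 1], [0, 0, 1, 1])
        assert mutual_information(t) == pytest.approx(np.log(2), abs=1e-12)

    def test_mi_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 5, size=40)
            b = rng.integers(0, 4, size=40)
            t = contingency(a, b)
            mi = mutual_information(t)
            ha = entropy(t.row_marginal / t.n)
            hb = entropy(t.col_marginal / t.n)
            assert mi <= min(ha, hb) + 1e-12
            assert mi >= -1e-12

    @pytest.mark.parametrize("k", [1, 2, 5, 9])
    def test_entropy_of_uniform_is_log_k(self, k):
        assert entropy(np.full(k, 1.0 / k)) == pytest.approx(np.log(k), abs=1e-12)

    def test_entropy_rejects_bad_input(self):
        with pytest.raises(ValueError):
            entropy([0.5, -0.5, 1.0])
        with pytest.raises(ValueError):
            entropy([0.4, 0.4])


class TestNMIAndARI:
    def test_identical_partitions_score_one(self):
        labs = [0, 1, 2, 0, 1, 2]
        assert nmi(labs, labs) == pytest.approx(1.0)
        assert ari(labs, labs) == pytest.approx(1.0)

    def test_independent_partitions_score_zero_nmi(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-15)

    def test_crossed_partition_ari_matches_pair_oracle(self):
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        assert ari(a, b) == pytest.approx(ari_pair_oracle(a, b), abs=1e-12)

    def test_against_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = rng.integers(0, rng.integers(2, 7), size=60)
            b = rng.integers(0, rng.integers(2, 7), size=60)
            assert nmi(a, b) == pytest.approx(normalized_mutual_info_score(a, b), abs=1e-10)
            assert ari(a, b) == pytest.approx(adjusted_rand_score(a, b), abs=1e-10)

    def test_relabeling_invariance_and_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 4, size=30)
        sigma = {0: "x", 1: "y", 2: "z"}
        a_renamed = [sigma[v] for v in a]
        assert ari(a, b) == pytest.approx(ari(a_renamed, list(b)), abs=1e-14)
        assert ari(a, b) == pytest.approx(ari(b, a), abs=1e-14)
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-14)

    def test_trivial_partitions_convention(self):
        assert nmi([0, 0, 0], ["x", "x", "x"]) == 1.0
        assert ari([0, 0, 0], ["x", "x", "x"]) == 1.0

    def test_random_vs_random_ari_centred_on_zero(self):
        rng = np.random.default_rng(4)
        values = [
            ari(rng.integers(0, 4, size=100), rng.integers(0, 4, size=100))
            for _ in range(1000)
        ]
        assert abs(np.mean(values)) < 0.02


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion(["a", "b", "a"], ["a", "b", "a"], "a")
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 1, 0)

    def test_all_predicted_positive(self):
        c = confusion(["a", "b", "b"], ["a", "a", "a"], "a")
        assert c.tn == 0 and c.fn == 0 and c.fp == 2

    def test_counts_partition_all_instances(self):
        rng = np.random.default_rng(5)
        truth = rng.choice(["a", "b", "c"], size=30)
        pred = rng.choice(["a", "b", "c"], size=30)
        c = confusion(list(truth), list(pred), "b")
        assert c.total == 30

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            confusion(["a"], ["a"], "z")

    def test_tpr_fpr_hand_values(self):
        tpr, fpr = tpr_fpr(ConfusionCounts(tp=3, fp=2, tn=4, fn=1))
        assert tpr == pytest.approx(0.75)
        assert fpr == pytest.approx(1 / 3)
        assert tpr_fpr(ConfusionCounts(8, 0, 5, 2)) == (0.8, 0.0)

    def test_empty_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            tpr, fpr = tpr_fpr(ConfusionCounts(0, 0, 5, 0))
        assert tpr == 0.0


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_constant_scores_give_auc_half(self):
        curve = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.5)

    def test_curve_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(6)
        curve = roc_auc(rng.random(40), rng.integers(0, 2, size=40))
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1

    def test_auc_equals_mann_whitney_statistic(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(7)
        for _ in range(50):
            y = rng.integers(0, 2, size=50)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(50), 2)  # ties likely
            ranks = rankdata(scores)
            n_pos, n_neg = y.sum(), len(y) - y.sum()
            u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
            assert roc_auc(scores, y).auc == pytest.approx(u / (n_pos * n_neg), abs=1e-10)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=100)
        scores = rng.random(100)
        assert roc_auc(scores, y).auc == pytest.approx(roc_auc_score(y, scores), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_macro_auc_averages_one_vs_rest(self):
        labels = ["a", "a", "b", "b"]
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert macro_auc(scores, labels, ["a", "b"]) == pytest.approx(1.0)


class TestKFold:
    def test_folds_partition_indices_with_balanced_sizes(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(2, min(n, 12) + 1))
            folds = kfold_indices(n, k, seed=int(rng.integers(1000)))
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1
            union = np.concatenate(folds)
            assert len(union) == n and set(union) == set(range(n))

    def test_leave_one_out_sizes(self):
        folds = kfold_indices(10, 10, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_stratified_folds_preserve_class_balance(self):
        labels = np.array([0] * 40 + [1] * 10)
        folds = kfold_indices(50, 5, seed=1, labels=labels)
        for f in folds:
            assert np.sum(labels[f] == 1) == 2  # 10 minority / 5 folds

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 6)

    def test_cv_on_separable_data_is_accurate(self, separable_embedding):
        X, labels = separable_embedding
        from sklearn.linear_model import LogisticRegression

        def trainer(X_tr, y_tr):
            clf = LogisticRegression().fit(X_tr, y_tr)
            return clf.predict

        result = kfold_cv(X, labels, trainer, CVConfig(k=10, seed=0))
        assert len(result.fold_accuracies) == 10
        assert result.mean_accuracy >= 0.95


class TestAccuracyAndReport:
    @pytest.mark.parametrize(
        "truth,pred,expected",
        [(["a", "b"], ["a", "b"], 1.0), (["a", "b"], ["b", "a"], 0.0), (list("aabb"), list("aabc"), 0.75)],
    )
    def test_accuracy_fraction(self, truth, pred, expected):
        assert accuracy(truth, pred) == expected

    def test_evaluate_report_contents(self):
        truth = ["a", "a", "b", "b"]
        pred = ["a", "b", "b", "b"]
        scores = np.array([[0.9, 0.1], [0.4, 0.6], [0.2, 0.8], [0.1, 0.9]])
        report = evaluate(truth, pred, scores, ["a", "b"])
        assert report["acc"] == 0.75
        assert set(report["per_class"]) == {"a", "b"}
        assert 0.0 <= report["macro_auc"] <= 1.0
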