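"""Evaluation metrics: contingency-based MI/entropy/NMI, ARI, confusion counts,
TPR/FPR, ROC/AUC, accuracy, and K-fold cross-validation.

All partition-agreement quantities are computed from a single contingency
table of joint label counts.  Mutual information uses natural logarithms
(NMI is base-invariant); NMI is the arithmetic normalization
2*MI / (H(A) + H(B)); ARI is the Hubert-Arabie permutation-adjusted Rand
index over pair counts.  ROC curves enumerate all distinct score thresholds
in descending order and AUC is the trapezoid area, which equals the
tie-corrected Mann-Whitney rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ContingencyTable",
    "ConfusionCounts",
    "ROCCurve",
    "CVConfig",
    "CVResult",
    "contingency",
    "mutual_information",
    "entropy",
    "nmi",
    "ari",
    "confusion",
    "tpr_fpr",
    "roc_auc",
    "macro_auc",
    "kfold_indices",
    "kfold_cv",
    "accuracy",
    "evaluate",
]


# ---------------------------------------------------------------------------
# contingency table and partition-agreement scores


@dataclass
class ContingencyTable:
    """Joint label counts between partition A (rows) and partition B (cols)."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _check_lengths(labels_a: Sequence, labels_b: Sequence) -> None:
    if len(labels_a) != len(labels_b):
        raise ValueError(f"label lists differ in length: {len(labels_a)} vs {len(labels_b)}")
    if len(labels_a) == 0:
        raise ValueError("empty label lists")


def contingency(labels_a: Sequence, labels_b: Sequence) -> ContingencyTable:
    """Count items per (A-label, B-label) combination."""
    _check_lengths(labels_a, labels_b)
    rows = tuple(sorted(set(labels_a)))
    cols = tuple(sorted(set(labels_b)))
    ri = {lab: i for i, lab in enumerate(rows)}
    ci = {lab: i for i, lab in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        counts[ri[a], ci[b]] += 1
    return ContingencyTable(counts, rows, cols)


def entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in nats; 0*log(1/0) := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(table: ContingencyTable) -> float:
    """MI of the two partitions from their joint counts, in nats."""
    n = table.n
    pij = table.counts / n
    pa = table.row_marginal / n
    pb = table.col_marginal / n
    outer = np.outer(pa, pb)
    nz = pij > 0
    return float(np.sum(pij[nz] * np.log(pij[nz] / outer[nz])))


def nmi(labels_a: Sequence, labels_b: Sequence) -> float:
    """Normalized mutual information: 2*MI / (H(A) + H(B)).

    If both partitions are trivial (single cluster each, so both entropies
    vanish) the convention is 1.0 when the partitions are identical and 0.0
    otherwise.
    """
    t = contingency(labels_a, labels_b)
    ha = entropy(t.row_marginal / t.n)
    hb = entropy(t.col_marginal / t.n)
    if ha + hb == 0.0:
        # both partitions have one cluster each, hence group the items
        # identically regardless of label names
        return 1.0
    return 2.0 * mutual_information(t) / (ha + hb)


def ari(labels_a: Sequence, labels_b: Sequence) -> float:
    """Hubert-Arabie adjusted Rand index from pair counts.

    (Index - Expected) / (Max - Expected); 1.0 when the denominator is
    degenerate (both partitions identical and trivial, e.g. all singletons
    or one cluster each).
    """
    _check_lengths(labels_a, labels_b)
    if len(labels_a) < 2:
        raise ValueError("ARI requires at least 2 items")
    t = contingency(labels_a, labels_b)
    n = t.n

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(t.counts).sum()
    sum_a = comb2(t.row_marginal).sum()
    sum_b = comb2(t.col_marginal).sum()
    total = comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# confusion counts, TPR/FPR, ROC/AUC


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels_true: Sequence, labels_pred: Sequence, positive_class) -> ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN counts for one positive class."""
    _check_lengths(labels_true, labels_pred)
    observed = set(labels_true) | set(labels_pred)
    if positive_class not in observed:
        raise ValueError(f"class {positive_class!r} absent from both label lists")
    tp = fp = tn = fn = 0
    for t, p in zip(labels_true, labels_pred):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def tpr_fpr(c: ConfusionCounts) -> tuple[float, float]:
    """TPR = TP/(TP+FN), FPR = FP/(TN+FP); empty denominators give 0.0."""
    import warnings

    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    fpr = c.fp / (c.tn + c.fp) if (c.tn + c.fp) > 0 else 0.0
    if (c.tp + c.fn) == 0 or (c.tn + c.fp) == 0:
        warnings.warn("empty denominator in TPR/FPR; reporting 0.0", stacklevel=2)
    return float(tpr), float(fpr)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels_binary: Sequence[int]) -> ROCCurve:
    """ROC curve over all distinct score thresholds (descending), AUC by trapezoids.

    ``labels_binary`` holds 0/1 with both classes present.  The curve starts
    at (0, 0) and ends at (1, 1); ties are collapsed into a single point.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels_binary)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels_binary must contain both classes 0 and 1")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    # indices where the score strictly drops: each is a threshold point
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], dtype=int)
    idx = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[idx]
    fps = (idx + 1) - tps
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, fpr, tpr, auc)


def macro_auc(score_matrix: np.ndarray, labels: Sequence, classes: Sequence) -> float:
    """Macro-averaged one-vs-rest AUC over the given class order.

    Classes absent from ``labels`` (or covering all of them) cannot anchor a
    ROC curve and are skipped.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    labels = list(labels)
    aucs = []
    for k, cls in enumerate(classes):
        y = np.array([1 if lab == cls else 0 for lab in labels])
        if y.min() == y.max():
            continue
        aucs.append(roc_auc(score_matrix[:, k], y).auc)
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# K-fold cross-validation


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = False


@dataclass
class CVResult:
    fold_accuracies: list[float]
    fold_indices: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def kfold_indices(n: int, k: int, seed: int = 0, labels: Sequence | None = None) -> list[np.ndarray]:
    """Seeded random partition of 0..n-1 into k folds with sizes differing by <= 1.

    With ``labels`` the split is stratified: each class is partitioned
    separately so class proportions are near-constant across folds.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    # round-robin over shuffled members of each class keeps fold sizes within 1
    offset = 0
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        for i, idx in enumerate(members):
            folds[(offset + i) % k].append(int(idx))
        offset += len(members)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_cv(
    X: np.ndarray,
    labels: Sequence,
    trainer: Callable[[np.ndarray, Sequence], Callable[[np.ndarray], Sequence]],
    config: CVConfig | None = None,
) -> CVResult:
    """K-fold cross-validation of a train-then-predict procedure.

    ``trainer(X_train, labels_train)`` must return a predict function
    mapping a feature matrix to labels.  Returns per-fold and mean accuracy.
    """
    config = config or CVConfig()
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = len(labels)
    folds = kfold_indices(n, config.k, config.seed, labels if config.stratified else None)
    fold_accs = []
    for fold in folds:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[fold] = True
        predict_fn = trainer(X[~test_mask], [labels[i] for i in np.flatnonzero(~test_mask)])
        pred = predict_fn(X[test_mask])
        truth = [labels[i] for i in fold]
        fold_accs.append(accuracy(truth, list(pred)))
    return CVResult(fold_accs, folds)


def accuracy(labels_true: Sequence, labels_pred: Sequence) -> float:
    """Fraction of exact label matches."""
    _check_lengths(labels_true, labels_pred)
    return float(np.mean([t == p for t, p in zip(labels_true, labels_pred)]))


def evaluate(
    labels_true: Sequence,
    labels_pred: Sequence,
    score_matrix: np.ndarray | None = None,
    classes: Sequence | None = None,
) -> dict:
    """Summary report: ACC, ARI, NMI, per-class TPR/FPR, and macro AUC if scores given."""
    report = {
        "acc": accuracy(labels_true, labels_pred),
        "ari": ari(labels_true, labels_pred),
        "nmi": nmi(labels_true, labels_pred),
        "per_class": {},
    }
    if classes is None:
        classes = sorted(set(labels_true))
    for cls in classes:
        c = confusion(labels_true, labels_pred, cls)
        tpr, fpr = tpr_fpr(c)
        report["per_class"][str(cls)] = {
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn, "tpr": tpr, "fpr": fpr,
        }
    if score_matrix is not None:
        report["macro_auc"] = macro_auc(score_matrix, labels_true, classes)
    return report
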