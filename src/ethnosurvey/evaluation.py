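"""Confusion-matrix metrics, ROC AUC, and the two resampling protocols.

Metrics follow the usual confusion-matrix definitions — accuracy, per-class
precision/recall/F-measure (combined weighted or macro), Cohen's kappa
(P0 - PC)/(1 - PC), and one-vs-rest ROC AUC via the midrank statistic.
Protocols: a stratified 70-30 holdout and stratified k-fold cross-validation
whose headline accuracy is the mean of per-fold accuracies, with the pooled
confusion matrix reported alongside.

All rates are reported as percentages rounded half-up at 2 decimals in the
formatted report; computation stays full precision.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifier import CLASSIFIERS, Classifier, TreeParams
from .preprocessing import FeatureTable

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: list[list[int]]       # rows = actual, columns = predicted

    @property
    def total(self) -> int:
        return int(sum(map(sum, self.counts)))

    def tp(self, i: int) -> int:
        return self.counts[i][i]

    def fp(self, i: int) -> int:
        return sum(row[i] for row in self.counts) - self.counts[i][i]

    def fn(self, i: int) -> int:
        return sum(self.counts[i]) - self.counts[i][i]

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fp(i) - self.fn(i)

    def support(self, i: int) -> int:
        return sum(self.counts[i])

    def add(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        merged = sorted(set(self.classes) | set(other.classes))
        counts = [[0] * len(merged) for _ in merged]
        for cm in (self, other):
            for a, row in zip(cm.classes, cm.counts):
                for p, v in zip(cm.classes, row):
                    counts[merged.index(a)][merged.index(p)] += v
        return ConfusionMatrix(merged, counts)


def confusion_matrix(truth: Sequence[str], predicted: Sequence[str],
                     classes: Sequence[str] | None = None) -> ConfusionMatrix:
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    if len(truth) == 0:
        raise ValueError("empty label sequences")
    labels = list(classes) if classes else sorted(set(truth) | set(predicted))
    idx = {c: i for i, c in enumerate(labels)}
    counts = [[0] * len(labels) for _ in labels]
    for a, p in zip(truth, predicted):
        counts[idx[a]][idx[p]] += 1
    return ConfusionMatrix(labels, counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Correct predictions over all predictions, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * sum(cm.tp(i) for i in range(len(cm.classes))) / cm.total


def precision_recall_f(cm: ConfusionMatrix,
                       averaging: str = "weighted") -> tuple[float, float, float]:
    """Per-class precision/recall/F combined by support weighting (the
    convention under which recall equals accuracy) or macro averaging."""
    if averaging not in ("weighted", "macro"):
        raise ValueError(f"unknown averaging {averaging!r}")
    precisions, recalls, fs, supports = [], [], [], []
    for i, c in enumerate(cm.classes):
        tp, fp, fn = cm.tp(i), cm.fp(i), cm.fn(i)
        if tp + fp == 0:
            log.warning("class %r never predicted; precision set to 0", c)
            p = 0.0
        else:
            p = tp / (tp + fp)
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precisions.append(p)
        recalls.append(r)
        fs.append(f)
        supports.append(cm.support(i))
    if averaging == "macro":
        w = [1.0] * len(supports)
    else:
        w = supports
    tot = sum(w)
    avg = lambda vals: 100.0 * sum(v * wi for v, wi in zip(vals, w)) / tot
    return avg(precisions), avg(recalls), avg(fs)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement in [-1, 1]."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p0 = sum(cm.tp(i) for i in range(len(cm.classes))) / total
    pc = sum(sum(cm.counts[i]) * sum(row[i] for row in cm.counts)
             for i in range(len(cm.classes))) / total ** 2
    if math.isclose(pc, 1.0):
        raise ValueError("kappa undefined: both marginals are degenerate")
    return (p0 - pc) / (1 - pc)


def roc_auc_ovr(truth: Sequence[str],
                scores: Sequence[dict[str, float]]) -> float:
    """One-vs-rest AUC per class via the midrank (Mann-Whitney) statistic,
    combined by support-weighted mean, in percent."""
    present = sorted(set(truth))
    if len(present) < 2:
        raise ValueError("AUC undefined for single-class truth")
    aucs, weights = [], []
    for c in present:
        y = np.array([1 if t == c else 0 for t in truth])
        s = np.array([sc.get(c, 0.0) for sc in scores], dtype=float)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        ranks = rankdata(s)  # midranks for ties
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
        weights.append(n_pos)
    return 100.0 * float(np.average(aucs, weights=weights))


# ---------------------------------------------------------------------------
# resampling protocols


def _subset(table: FeatureTable, idx: Sequence[int]) -> FeatureTable:
    return FeatureTable(feature_names=list(table.feature_names),
                        records=[table.records[i] for i in idx],
                        classes=[table.classes[i] for i in idx],
                        encoding=table.encoding)


def holdout_split(table: FeatureTable, test_fraction: float = 0.3,
                  seed: int = 42) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split with round()-based test sizing.

    The test size is round(test_fraction * n); per-class quotas are
    apportioned by largest remainder so they reconcile to that total.
    Classes with fewer than two records go to the training side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(table)
    target = math.floor(test_fraction * n + 0.5)
    rng = np.random.default_rng(seed)

    by_class: dict[str, list[int]] = {}
    for i, c in enumerate(table.classes):
        by_class.setdefault(c, []).append(i)

    small = {c for c, idx in by_class.items() if len(idx) < 2}
    for c in sorted(small):
        log.warning("class %r has <2 records; assigned to training side", c)
    eligible = sorted(c for c in by_class if c not in small)
    quotas = {c: test_fraction * len(by_class[c]) for c in eligible}
    base = {c: min(int(math.floor(quotas[c])), len(by_class[c]) - 1)
            for c in eligible}
    remaining = target - sum(base.values())
    by_frac = sorted(eligible, key=lambda c: (-(quotas[c] - math.floor(quotas[c])),
                                              -len(by_class[c]), c))
    take = dict(base)
    for c in by_frac:
        if remaining <= 0:
            break
        if take[c] < len(by_class[c]) - 1:
            take[c] += 1
            remaining -= 1

    test_idx: list[int] = []
    for c in eligible:
        perm = rng.permutation(by_class[c])
        test_idx.extend(int(i) for i in perm[:take[c]])
    test_set = set(test_idx)
    train_idx = [i for i in range(n) if i not in test_set]
    return _subset(table, train_idx), _subset(table, sorted(test_idx))


@dataclass
class EvaluationReport:
    protocol: str                     # "cv10" | "holdout7030"
    seed: int
    averaging: str
    accuracy: float                   # percent; CV: mean of per-fold accuracies
    precision: float
    recall: float
    f_measure: float
    kappa: float | None
    roc_auc: float | None
    confusion: ConfusionMatrix
    per_fold_accuracy: list[float] = field(default_factory=list)

    def formatted(self) -> dict:
        r2 = lambda v: None if v is None else math.floor(v * 100 + 0.5) / 100
        return {
            "protocol": self.protocol, "seed": self.seed,
            "averaging": self.averaging,
            "accuracy": r2(self.accuracy), "precision": r2(self.precision),
            "recall": r2(self.recall), "f_measure": r2(self.f_measure),
            "kappa": r2(self.kappa), "roc_auc": r2(self.roc_auc),
            "per_fold_accuracy": [r2(a) for a in self.per_fold_accuracy],
            "confusion": {"classes": self.confusion.classes,
                          "counts": self.confusion.counts},
        }


def _make_classifier(classifier, params) -> Classifier:
    if callable(classifier) and not isinstance(classifier, str):
        return classifier()
    factory = CLASSIFIERS[classifier or "tree"]
    if factory is CLASSIFIERS.get("tree"):
        return factory(params or TreeParams())
    return factory()


def _evaluate(cm: ConfusionMatrix, truth, scores, protocol, seed, averaging,
              per_fold=None, headline=None) -> EvaluationReport:
    p, r, f = precision_recall_f(cm, averaging)
    try:
        auc = roc_auc_ovr(truth, scores)
    except ValueError:
        auc = None
    try:
        kappa = cohens_kappa(cm)
    except ValueError:
        kappa = None
    return EvaluationReport(
        protocol=protocol, seed=seed, averaging=averaging,
        accuracy=headline if headline is not None else accuracy(cm),
        precision=p, recall=r, f_measure=f, kappa=kappa,
        roc_auc=auc, confusion=cm, per_fold_accuracy=per_fold or [])


def evaluate_holdout(table: FeatureTable, classifier="tree",
                     params: TreeParams | None = None,
                     test_fraction: float = 0.3, seed: int = 42,
                     averaging: str = "weighted") -> EvaluationReport:
    """Fit on the training side of a stratified split, evaluate on the rest."""
    train, test = holdout_split(table, test_fraction, seed)
    clf = _make_classifier(classifier, params)
    clf.fit(train)
    preds = [clf.predict(r) for r in test.records]
    scores = [clf.predict_scores(r) for r in test.records]
    cm = confusion_matrix(test.classes, preds,
                          sorted(set(table.classes)))
    return _evaluate(cm, test.classes, scores, "holdout7030", seed, averaging)


def kfold_cv(table: FeatureTable, k: int = 10, seed: int = 42,
             classifier="tree", params: TreeParams | None = None,
             averaging: str = "weighted") -> EvaluationReport:
    """Stratified k-fold cross-validation.

    Every record is tested exactly once; the pooled confusion matrix feeds the
    agreement metrics while the headline accuracy is the mean of the per-fold
    accuracies.
    """
    n = len(table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of records {n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    labels = sorted(set(table.classes))
    pooled = ConfusionMatrix(labels, [[0] * len(labels) for _ in labels])
    truths: list[str] = []
    all_scores: list[dict[str, float]] = []
    fold_acc: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # sparse-class folds
        splits = list(skf.split(np.zeros(n), table.classes))
    for train_idx, test_idx in splits:
        clf = _make_classifier(classifier, params)
        clf.fit(_subset(table, train_idx))
        test = _subset(table, test_idx)
        preds = [clf.predict(r) for r in test.records]
        all_scores.extend(clf.predict_scores(r) for r in test.records)
        truths.extend(test.classes)
        fold_cm = confusion_matrix(test.classes, preds, labels)
        fold_acc.append(accuracy(fold_cm))
        pooled = pooled.add(fold_cm)
    headline = float(np.mean(fold_acc))
    return _evaluate(pooled, truths, all_scores, f"cv{k}", seed, averaging,
                     per_fold=fold_acc, headline=headline)
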