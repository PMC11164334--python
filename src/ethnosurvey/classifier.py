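"""Gain-ratio decision-tree induction over categorical survey features.

A reference C4.5-style inducer: multiway splits (one branch per observed
nominal value), gain ratio as the split criterion, majority-class leaves,
optional pessimistic error-based pruning, and deterministic tie-breaks so that
identical inputs always yield structurally identical trees.  A small plug-in
contract lets alternative learners (e.g. scikit-learn estimators) be evaluated
through the same interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

from scipy.stats import beta as beta_dist

from .preprocessing import FeatureTable

# ---------------------------------------------------------------------------
# information measures


def entropy(class_counts: Sequence[int]) -> float:
    """Shannon entropy in bits of a class-count vector."""
    total = sum(class_counts)
    if total <= 0:
        raise ValueError("entropy of an empty node is undefined")
    h = 0.0
    for c in class_counts:
        if c < 0:
            raise ValueError("negative class count")
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def _class_counts(classes: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in classes:
        out[c] = out.get(c, 0) + 1
    return out


def gain_ratio(table: FeatureTable, feature: str) -> float:
    """Information gain of splitting on ``feature`` divided by the split
    information; constant features return 0."""
    if feature not in table.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    return _gain_ratio(table.records, table.classes, feature)[0]


def _gain_ratio(records, classes, feature) -> tuple[float, float]:
    n = len(records)
    base = entropy(list(_class_counts(classes).values()))
    groups: dict[str, list[str]] = {}
    for rec, cls in zip(records, classes):
        groups.setdefault(rec[feature], []).append(cls)
    if len(groups) < 2:
        return 0.0, 0.0
    cond = sum(len(g) / n * entropy(list(_class_counts(g).values()))
               for g in groups.values())
    gain = base - cond
    split_info = entropy([len(g) for g in groups.values()])
    if split_info <= 0:
        return 0.0, gain
    return max(0.0, gain) / split_info, gain


# ---------------------------------------------------------------------------
# tree model


@dataclass
class TreeParams:
    min_leaf: int = 2
    pruning: str = "pessimistic"       # "none" | "pessimistic"
    confidence: float = 0.25
    tie_break: str = "feature_order"

    def __post_init__(self):
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0 < self.confidence < 0.5:
            raise ValueError("confidence must lie in (0, 0.5)")
        if self.pruning not in ("none", "pessimistic"):
            raise ValueError(f"unknown pruning mode {self.pruning!r}")


@dataclass
class TreeNode:
    prediction: str                         # majority class at this node
    counts: dict[str, int]                  # training class frequencies
    feature: str | None = None              # None for leaves
    children: dict[str, "TreeNode"] = field(default_factory=dict)
    fallback: str | None = None             # child key for unseen values

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class TreeModel:
    root: TreeNode
    feature_names: list[str]
    classes: list[str]                      # fixed label order for scores
    params: TreeParams

    def n_leaves(self) -> int:
        def walk(node):
            return 1 if node.is_leaf else sum(walk(c) for c in node.children.values())
        return walk(self.root)

    def depth(self) -> int:
        def walk(node):
            return 0 if node.is_leaf else 1 + max(walk(c) for c in node.children.values())
        return walk(self.root)


def _majority(counts: dict[str, int], parent_counts: dict[str, int] | None) -> str:
    """Majority class; ties broken by parent frequency then lexicographically."""
    best = max(counts.values())
    tied = sorted(c for c, v in counts.items() if v == best)
    if len(tied) > 1 and parent_counts:
        parent_best = max(parent_counts.get(c, 0) for c in tied)
        tied = sorted(c for c in tied if parent_counts.get(c, 0) == parent_best)
    return tied[0]


def _pessimistic_errors(counts: dict[str, int], confidence: float) -> float:
    """C4.5 upper-confidence-bound error estimate for a leaf."""
    n = sum(counts.values())
    if n == 0:
        return 0.0
    errors = n - max(counts.values())
    # upper CF bound of a binomial proportion with `errors` of `n` observed
    upper = beta_dist.ppf(1.0 - confidence, errors + 1, n - errors)
    return n * float(upper)


def fit_tree(table: FeatureTable, params: TreeParams | None = None) -> TreeModel:
    """Grow a gain-ratio tree by recursive partitioning.

    Stops when a node is pure, no informative feature remains, or the node is
    smaller than ``2 * min_leaf``; a split must leave at least two branches
    with ``min_leaf`` records.  Each feature is used at most once per path.
    """
    params = params or TreeParams()
    if len(table) == 0:
        raise ValueError("cannot fit a tree on an empty table")

    def build(records, classes, available, parent_counts):
        counts = _class_counts(classes)
        node = TreeNode(prediction=_majority(counts, parent_counts), counts=counts)
        if len(counts) == 1 or not available or len(records) < 2 * params.min_leaf:
            return node
        scored = []
        for f in available:
            gr, gain = _gain_ratio(records, classes, f)
            if gr > 0 and gain > 1e-12:
                scored.append((gr, f))
        if not scored:
            return node
        best_gr = max(gr for gr, _ in scored)
        # tie-break: earliest feature in declared order
        order = {f: i for i, f in enumerate(table.feature_names)}
        best_f = min((f for gr, f in scored if abs(gr - best_gr) < 1e-12),
                     key=lambda f: order[f])
        groups: dict[str, tuple[list, list]] = {}
        for rec, cls in zip(records, classes):
            groups.setdefault(rec[best_f], (list(), list()))
            groups[rec[best_f]][0].append(rec)
            groups[rec[best_f]][1].append(cls)
        if sum(1 for g, _ in groups.values() if len(g) >= params.min_leaf) < 2:
            return node
        node.feature = best_f
        remaining = [f for f in available if f != best_f]
        for value in sorted(groups):
            g_rec, g_cls = groups[value]
            node.children[value] = build(g_rec, g_cls, remaining, counts)
        node.fallback = max(sorted(node.children),
                            key=lambda v: node.children[v].n)
        return node

    root = build(table.records, table.classes, list(table.feature_names), None)
    model = TreeModel(root=root, feature_names=list(table.feature_names),
                      classes=sorted(set(table.classes)), params=params)
    if params.pruning == "pessimistic":
        _prune(model.root, params.confidence)
    return model


def _prune(node: TreeNode, confidence: float) -> float:
    """Bottom-up subtree replacement: collapse a split whose estimated error
    is no better than predicting the majority class outright."""
    if node.is_leaf:
        return _pessimistic_errors(node.counts, confidence)
    subtree_err = sum(_prune(child, confidence) for child in node.children.values())
    leaf_err = _pessimistic_errors(node.counts, confidence)
    if leaf_err <= subtree_err + 0.1:
        node.feature = None
        node.children = {}
        node.fallback = None
        return leaf_err
    return subtree_err


def predict(model: TreeModel, record: dict) -> str:
    """Route a record to a leaf; unseen feature values take the fallback
    (largest-mass) branch."""
    node = model.root
    while not node.is_leaf:
        if node.feature not in record:
            raise KeyError(f"record lacks feature {node.feature!r}")
        value = record[node.feature]
        node = node.children.get(value) or node.children[node.fallback]
    return node.prediction


def predict_scores(model: TreeModel, record: dict) -> dict[str, float]:
    """Per-class scores from the routed leaf's Laplace-smoothed frequencies."""
    node = model.root
    while not node.is_leaf:
        value = record.get(node.feature)
        if value is None:
            raise KeyError(f"record lacks feature {node.feature!r}")
        node = node.children.get(value) or node.children[node.fallback]
    k = len(model.classes)
    total = node.n + k
    return {c: (node.counts.get(c, 0) + 1) / total for c in model.classes}


# ---------------------------------------------------------------------------
# serialization


def _node_to_dict(node: TreeNode) -> dict:
    d = {"prediction": node.prediction, "counts": node.counts}
    if not node.is_leaf:
        d["feature"] = node.feature
        d["fallback"] = node.fallback
        d["children"] = {v: _node_to_dict(c) for v, c in node.children.items()}
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(prediction=d["prediction"],
                    counts={k: int(v) for k, v in d["counts"].items()})
    if "feature" in d:
        node.feature = d["feature"]
        node.fallback = d["fallback"]
        node.children = {v: _node_from_dict(c) for v, c in d["children"].items()}
    return node


def model_to_json(model: TreeModel) -> str:
    return json.dumps({
        "feature_names": model.feature_names,
        "classes": model.classes,
        "params": {"min_leaf": model.params.min_leaf,
                   "pruning": model.params.pruning,
                   "confidence": model.params.confidence,
                   "tie_break": model.params.tie_break},
        "root": _node_to_dict(model.root),
    }, indent=2)


def model_from_json(text: str) -> TreeModel:
    d = json.loads(text)
    return TreeModel(root=_node_from_dict(d["root"]),
                     feature_names=d["feature_names"], classes=d["classes"],
                     params=TreeParams(**d["params"]))


# ---------------------------------------------------------------------------
# plug-in contract


class Classifier(Protocol):
    """Anything that can be evaluated by the resampling protocols."""

    def fit(self, table: FeatureTable) -> None: ...
    def predict(self, record: dict) -> str: ...
    def predict_scores(self, record: dict) -> dict[str, float]: ...


class GainRatioTree:
    """The reference tree behind the :class:`Classifier` contract."""

    def __init__(self, params: TreeParams | None = None):
        self.params = params or TreeParams()
        self.model: TreeModel | None = None

    def fit(self, table: FeatureTable) -> None:
        self.model = fit_tree(table, self.params)

    def predict(self, record: dict) -> str:
        return predict(self.model, record)

    def predict_scores(self, record: dict) -> dict[str, float]:
        return predict_scores(self.model, record)


class SklearnAdapter:
    """Wrap a scikit-learn estimator (with ``predict_proba``) so it honours
    the same contract via one-hot encoding of the nominal features."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._columns: list[tuple[str, str]] = []
        self._classes: list[str] = []

    def _encode(self, record: dict) -> list[float]:
        return [1.0 if record.get(f) == v else 0.0 for f, v in self._columns]

    def fit(self, table: FeatureTable) -> None:
        vocab = {f: table.vocabulary(f) for f in table.feature_names}
        self._columns = [(f, v) for f in table.feature_names for v in vocab[f]]
        X = [self._encode(r) for r in table.records]
        self.estimator.fit(X, table.classes)
        self._classes = list(self.estimator.classes_)

    def predict(self, record: dict) -> str:
        scores = self.predict_scores(record)
        best = max(scores.values())
        return sorted(c for c, s in scores.items() if s == best)[0]

    def predict_scores(self, record: dict) -> dict[str, float]:
        proba = self.estimator.predict_proba([self._encode(record)])[0]
        return dict(zip(self._classes, map(float, proba)))


CLASSIFIERS = {"tree": GainRatioTree}


def register_classifier(name: str, factory) -> None:
    CLASSIFIERS[name] = factory
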