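"""Classification trees on MD profiles: CART with cost-complexity pruning.

Recursive binary partitioning with the Gini impurity criterion.  At every
node with at least ``minsplit`` observations and positive impurity, the
(feature, threshold) pair maximizing the impurity decrease is chosen over
the midpoints of adjacent sorted unique feature values.  The convention is
the clinical one: the *left* branch is taken when ``feature < threshold``
holds.  Ties break deterministically towards the lowest feature index, then
the smallest threshold, so a table always yields the same tree.

Pruning is weakest-link cost-complexity on the resubstitution
misclassification risk scaled by the root risk: an internal node's link
strength is

    g(t) = (R(t) - R(T_t)) / ((|leaves(T_t)| - 1) * R(root)),

and subtrees with g below the complexity parameter ``cp`` are collapsed,
weakest first, until all remaining links are worth their splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MD_FEATURES
from .intervals import clopper_pearson, wilson


@dataclass
class TreeFitParams:
    minsplit: int = 5
    complexity_parameter: float = 0.1
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.minsplit < 2:
            raise ValueError("minsplit must be >= 2")
        if self.complexity_parameter < 0:
            raise ValueError("cp must be >= 0")


@dataclass
class SplitNode:
    """A node of the fitted tree; leaves have ``feature is None``."""

    class_counts: np.ndarray
    n_total: int
    classes: tuple[str, ...]
    feature: str | None = None
    threshold: float | None = None
    left: "SplitNode | None" = None
    right: "SplitNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    @property
    def majority_class(self) -> str:
        # Deterministic tie-break: first class in the declared (sorted) order.
        return self.classes[int(np.argmax(self.class_counts))]

    @property
    def node_fraction(self) -> float:
        return self.n / self.n_total

    def misclassified(self) -> int:
        return self.n - int(self.class_counts.max())

    def leaves(self) -> list["SplitNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def subtree_misclassified(self) -> int:
        return sum(leaf.misclassified() for leaf in self.leaves())

    def n_internal(self) -> int:
        return 0 if self.is_leaf else 1 + self.left.n_internal() + self.right.n_internal()

    def to_dict(self) -> dict:
        d = {
            "class_counts": {c: int(k) for c, k in zip(self.classes, self.class_counts)},
            "majority_class": self.majority_class,
            "node_fraction": self.node_fraction,
        }
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=float(self.threshold),
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d

    def rules_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        frac = f"{100 * self.node_fraction:.0f}%"
        counts = "/".join(str(int(c)) for c in self.class_counts)
        head = f"{pad}[{self.majority_class}] ({counts}; {frac})"
        if self.is_leaf:
            return head
        return "\n".join([
            f"{head} split: {self.feature} < {self.threshold:.4g}",
            self.left.rules_text(indent + 1),
            self.right.rules_text(indent + 1),
        ])


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(x: np.ndarray, y: np.ndarray, n_classes: int
                ) -> tuple[int, float, float] | None:
    """Exhaustive-equivalent vectorized search for the best (feature, threshold).

    Returns (feature_index, threshold, impurity_decrease) or None if no
    split with positive decrease exists.  Thresholds are midpoints of
    adjacent distinct sorted values; ties prefer the lowest feature index,
    then the smallest threshold.
    """
    n, p = x.shape
    parent = _gini(np.bincount(y, minlength=n_classes).astype(float))
    best: tuple[int, float, float] | None = None
    for j in range(p):
        order = np.argsort(x[:, j], kind="stable")
        xs = x[order, j]
        ys = y[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left_counts = np.cumsum(onehot, axis=0)          # after i+1 points
        total = left_counts[-1]
        boundaries = np.nonzero(np.diff(xs) > 0)[0]      # split after index i
        if boundaries.size == 0:
            continue
        nl = boundaries + 1.0
        nr = n - nl
        lc = left_counts[boundaries]
        rc = total - lc
        gini_l = 1.0 - np.sum((lc / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((rc / nr[:, None]) ** 2, axis=1)
        decrease = parent - (nl / n) * gini_l - (nr / n) * gini_r
        # Features iterate in ascending index and thresholds ascend within a
        # feature, so "replace only on strict improvement" implements the
        # documented tie-break (lowest feature index, then smallest threshold).
        for i, dec in zip(boundaries, decrease):
            if dec > 1e-12 and (best is None or dec > best[2] + 1e-12):
                best = (j, float(0.5 * (xs[i] + xs[i + 1])), float(dec))
    return best


def fit_cart(table: pd.DataFrame, params: TreeFitParams | None = None,
             features: tuple[str, ...] = MD_FEATURES,
             label_col: str = "group") -> SplitNode:
    """Grow the full tree (before pruning) on a complete-feature table."""
    params = params or TreeFitParams()
    if len(table) == 0:
        raise ValueError("empty table")
    x = table[list(features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("missing feature values; apply the metrics missing policy first")
    classes = tuple(sorted(table[label_col].astype(str).unique().tolist()))
    y = np.array([classes.index(v) for v in table[label_col].astype(str)])
    n_total = len(y)

    def grow(idx: np.ndarray, depth: int) -> SplitNode:
        counts = np.bincount(y[idx], minlength=len(classes)).astype(float)
        node = SplitNode(class_counts=counts, n_total=n_total, classes=classes)
        if (len(idx) < params.minsplit or _gini(counts) == 0.0
                or (params.max_depth is not None and depth >= params.max_depth)):
            return node
        found = _best_split(x[idx], y[idx], len(classes))
        if found is None:
            return node
        j, thr, _ = found
        mask = x[idx, j] < thr
        node.feature = features[j]
        node.threshold = thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(n_total), 0)


def prune_tree(tree: SplitNode, cp: float = 0.1) -> SplitNode:
    """Weakest-link cost-complexity pruning at complexity parameter ``cp``.

    Collapses, weakest link first, every subtree whose per-split decrease in
    resubstitution error relative to the root error falls below ``cp``.
    ``cp = 0`` leaves the tree unchanged; a large ``cp`` collapses it to a
    single majority-class leaf.
    """
    tree = _copy(tree)
    root_risk = tree.misclassified()
    if root_risk == 0:
        # A pure root cannot justify any split under a positive cp.
        if cp > 0:
            return SplitNode(class_counts=tree.class_counts, n_total=tree.n_total,
                             classes=tree.classes)
        return tree
    while True:
        weakest: tuple[float, SplitNode] | None = None
        stack = [tree]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            n_splits = len(node.leaves()) - 1
            g = (node.misclassified() - node.subtree_misclassified()) / (n_splits * root_risk)
            if weakest is None or g < weakest[0] - 1e-12:
                weakest = (g, node)
            stack.extend([node.left, node.right])
        if weakest is None or weakest[0] >= cp - 1e-12:
            return tree
        _, node = weakest
        node.feature = None
        node.threshold = None
        node.left = None
        node.right = None


def _copy(node: SplitNode) -> SplitNode:
    new = SplitNode(class_counts=node.class_counts.copy(), n_total=node.n_total,
                    classes=node.classes, feature=node.feature, threshold=node.threshold)
    if not node.is_leaf:
        new.left = _copy(node.left)
        new.right = _copy(node.right)
    return new


def predict(tree: SplitNode, profile: dict | pd.Series) -> str:
    """Route one profile down the tree; strict ``feature < threshold`` goes left."""
    node = tree
    while not node.is_leaf:
        v = profile[node.feature]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing feature {node.feature!r} on the routed path")
        node = node.left if float(v) < node.threshold else node.right
    return node.majority_class


def predict_table(tree: SplitNode, table: pd.DataFrame) -> np.ndarray:
    return np.array([predict(tree, row) for _, row in table.iterrows()])


@dataclass
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray           # true x predicted
    accuracy: float
    ci95: tuple[float, float]
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.astype(int).tolist(),
            "accuracy": self.accuracy,
            "ci95": list(self.ci95),
            "n": self.n,
        }


def evaluate(tree: SplitNode, table: pd.DataFrame, label_col: str = "group",
             ci_method: str = "exact") -> ConfusionMatrix:
    """Resubstitution confusion matrix with an exact binomial CI on accuracy."""
    if len(table) == 0:
        raise ValueError("empty table")
    classes = tree.classes
    pred = predict_table(tree, table)
    true = table[label_col].astype(str).to_numpy()
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(true, pred):
        counts[classes.index(t), classes.index(p)] += 1
    correct = int(np.trace(counts))
    n = len(table)
    ci = clopper_pearson(correct, n) if ci_method == "exact" else wilson(correct, n)
    return ConfusionMatrix(classes=classes, counts=counts,
                           accuracy=correct / n, ci95=ci, n=n)


def tree_to_json(tree: SplitNode, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2)
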