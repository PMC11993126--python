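"""CART: split search, pruning, prediction, evaluation.

The reference oracles here are intentionally naive re-implementations:
an exhaustive recursive split search with plain Python loops, and a
brute-force enumeration of all pruned subtrees minimizing
error + cp * |splits|.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from photopheno.tree import (ConfusionMatrix, TreeFitParams, evaluate, fit_cart,
                             predict, predict_table, prune_tree)


# --- naive oracle -----------------------------------------------------------

def _gini(labels):
    n = len(labels)
    if n == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    return 1.0 - sum((c / n) ** 2 for c in counts)


def _oracle_best_split(x, y):
    n, p = x.shape
    parent = _gini(y)
    best = None
    for j in range(p):
        vals = sorted(set(x[:, j]))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2.0
            mask = x[:, j] < thr
            dec = parent - (mask.sum() / n) * _gini(y[mask]) \
                - ((~mask).sum() / n) * _gini(y[~mask])
            if dec > 1e-12 and (best is None or dec > best[2] + 1e-12):
                best = (j, thr, dec)
    return best


def _oracle_grow(x, y, minsplit):
    if len(y) < minsplit or _gini(y) == 0:
        return None
    found = _oracle_best_split(x, y)
    if found is None:
        return None
    j, thr, _ = found
    mask = x[:, j] < thr
    return (j, thr, _oracle_grow(x[mask], y[mask], minsplit),
            _oracle_grow(x[~mask], y[~mask], minsplit))


def _tree_to_tuple(node, features):
    if node.is_leaf:
        return None
    return (features.index(node.feature), node.threshold,
            _tree_to_tuple(node.left, features), _tree_to_tuple(node.right, features))


def _tuples_equal(a, b):
    if a is None or b is None:
        return a is b
    return (a[0] == b[0] and abs(a[1] - b[1]) < 1e-9
            and _tuples_equal(a[2], b[2]) and _tuples_equal(a[3], b[3]))


def _random_table(rng, n, classes=("a", "b", "c")):
    return pd.DataFrame({
        "f0": rng.normal(size=n).round(2),
        "f1": rng.normal(size=n).round(2),
        "group": rng.choice(classes, size=n),
    })


class TestFitCart:
    def test_perfect_1d_separation_single_split(self):
        table = pd.DataFrame({"f0": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0],
                              "group": list("aaabbb")})
        t = fit_cart(table, TreeFitParams(minsplit=2), features=("f0",))
        assert t.feature == "f0"
        assert t.threshold == pytest.approx(5.0)
        assert t.left.is_leaf and t.right.is_leaf

    def test_minsplit_stops_splitting(self):
        table = pd.DataFrame({"f0": [1.0, 2.0, 3.0, 4.0], "group": list("aabb")})
        t = fit_cart(table, TreeFitParams(minsplit=5), features=("f0",))
        assert t.is_leaf

    def test_matches_exhaustive_oracle_on_small_tables(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 31))
            table = _random_table(rng, n)
            params = TreeFitParams(minsplit=5)
            mine = fit_cart(table, params, features=("f0", "f1"))
            x = table[["f0", "f1"]].to_numpy()
            y = table["group"].to_numpy()
            oracle = _oracle_grow(x, y, params.minsplit)
            assert _tuples_equal(_tree_to_tuple(mine, ("f0", "f1")), oracle)

    def test_deterministic_and_row_order_invariant(self, rng):
        table = _random_table(rng, 40)
        t1 = fit_cart(table, features=("f0", "f1"))
        t2 = fit_cart(table.sample(frac=1.0, random_state=1), features=("f0", "f1"))
        assert _tuples_equal(_tree_to_tuple(t1, ("f0", "f1")),
                             _tree_to_tuple(t2, ("f0", "f1")))

    def test_child_counts_sum_to_parent(self, study_scale_cohort_md):
        t = fit_cart(study_scale_cohort_md)
        stack = [t]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                assert np.array_equal(node.class_counts,
                                      node.left.class_counts + node.right.class_counts)
                stack.extend([node.left, node.right])

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            fit_cart(pd.DataFrame({"f0": [], "group": []}), features=("f0",))


class TestPruning:
    def _planted_three_rule_table(self):
        # Three exact rules plus one weakly informative extra dimension that
        # seduces the full tree into a fourth, spurious split.
        rows = []
        rng = np.random.default_rng(5)
        for i in range(60):
            f0, f1, f2 = rng.normal(size=3)
            spur = rng.normal()
            if f0 < 0:
                label = "a"
            elif f1 < 0:
                label = "b"
            elif f2 < 0:
                label = "c"
            else:
                label = "d" if spur < 1.2 else "c"  # a few stragglers
            rows.append((f0, f1, f2, spur, label))
        return pd.DataFrame(rows, columns=["f0", "f1", "f2", "f3", "group"])

    def test_cp_zero_is_identity(self, study_scale_cohort_md):
        full = fit_cart(study_scale_cohort_md)
        assert prune_tree(full, 0.0).n_internal() == full.n_internal()

    def test_large_cp_collapses_to_majority_leaf(self, study_scale_cohort_md):
        root = prune_tree(fit_cart(study_scale_cohort_md), 10.0)
        assert root.is_leaf
        assert root.majority_class == "RP"

    def test_matches_subtree_enumeration_oracle(self):
        table = self._planted_three_rule_table()
        features = ("f0", "f1", "f2", "f3")
        full = fit_cart(table, TreeFitParams(minsplit=5), features=features)
        cp = 0.1
        pruned = prune_tree(full, cp)
        assert pruned.n_internal() == 3

        # Oracle: enumerate every pruned subtree, minimize
        # error/root_error + cp * n_splits; the weakest-link result must
        # attain the optimum.
        root_err = full.misclassified()

        def enumerate_subtrees(node):
            # Each subtree is represented by (n_splits, subtree_error).
            leaf = [(0, node.misclassified())]
            if node.is_leaf:
                return leaf
            combos = []
            for ls, le in enumerate_subtrees(node.left):
                for rs, re in enumerate_subtrees(node.right):
                    combos.append((1 + ls + rs, le + re))
            return leaf + combos

        costs = [err / root_err + cp * s for s, err in enumerate_subtrees(full)]
        mine = pruned.subtree_misclassified() / root_err + cp * (len(pruned.leaves()) - 1)
        assert mine == pytest.approx(min(costs))

    def test_resubstitution_error_non_increasing_in_size(self, study_scale_cohort_md):
        full = fit_cart(study_scale_cohort_md)
        errs = []
        for cp in (10.0, 0.3, 0.1, 0.02, 0.0):
            p = prune_tree(full, cp)
            errs.append((p.n_internal(), p.subtree_misclassified()))
        sizes, miss = zip(*errs)
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        assert all(a >= b for a, b in zip(miss, miss[1:]))


class TestPredict:
    def test_root_leaf_predicts_majority(self):
        table = pd.DataFrame({"f0": [1.0, 2.0, 3.0], "group": ["a", "a", "b"]})
        t = fit_cart(table, TreeFitParams(minsplit=99), features=("f0",))
        assert predict(t, {"f0": 123.0}) == "a"

    def test_strict_inequality_convention(self):
        table = pd.DataFrame({"f0": [1.0, 2.0, 3.0, 4.0], "group": list("aabb")})
        t = fit_cart(table, TreeFitParams(minsplit=2), features=("f0",))
        thr = t.threshold
        assert predict(t, {"f0": thr - 1e-9}) == "a"   # strictly below -> left
        assert predict(t, {"f0": thr}) == "b"          # equal -> right

    def test_missing_feature_raises(self):
        table = pd.DataFrame({"f0": [1.0, 2.0, 3.0, 4.0], "group": list("aabb")})
        t = fit_cart(table, TreeFitParams(minsplit=2), features=("f0",))
        with pytest.raises(ValueError, match="missing feature"):
            predict(t, {"f0": float("nan")})

    def test_planted_rule_cohort_matches_direct_rule_evaluation(self, study_scale_cohort_md):
        # The pruned study tree is a three-rule walk; applying the rules by
        # hand must agree with tree routing for every patient.
        t = prune_tree(fit_cart(study_scale_cohort_md), 0.1)
        preds = predict_table(t, study_scale_cohort_md)

        def by_hand(row, node=t):
            while not node.is_leaf:
                node = node.left if row[node.feature] < node.threshold else node.right
            return node.majority_class

        manual = np.array([by_hand(r) for _, r in study_scale_cohort_md.iterrows()])
        assert np.array_equal(preds, manual)


class TestEvaluate:
    def test_perfect_classifier(self):
        table = pd.DataFrame({"f0": np.r_[np.zeros(5), np.ones(5)],
                              "group": ["a"] * 5 + ["b"] * 5})
        t = fit_cart(table, TreeFitParams(minsplit=2), features=("f0",))
        cm = evaluate(t, table)
        assert cm.accuracy == 1.0
        assert cm.ci95[1] == 1.0

    @pytest.mark.parametrize("correct,n,expected", [
        (33, 50, (0.51, 0.79)),
        (25, 50, (0.36, 0.64)),
        (43, 50, (0.73, 0.94)),
    ])
    def test_printed_accuracy_cis(self, correct, n, expected):
        from photopheno.intervals import clopper_pearson

        lo, hi = clopper_pearson(correct, n)
        assert round(lo, 2) == expected[0]
        assert round(hi, 2) == expected[1]


def test_agrees_with_rpart_reference_on_clean_rules(tmp_path):
    """Cross-check against R's recursive-partitioning reference on a table
    with unambiguous splits (no minbucket edge cases)."""
    rng = np.random.default_rng(11)
    n = 40
    f0 = np.r_[rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n - n // 2)]
    f1 = rng.normal(size=n)
    group = np.where(f0 < 1.5, "a", "b")
    table = pd.DataFrame({"f0": f0, "f1": f1, "group": group})
    csv = tmp_path / "d.csv"
    table.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        library(rpart)
        d <- read.csv("{csv}")
        fit <- rpart(group ~ f0 + f1, data = d, method = "class",
                     control = rpart.control(minsplit = 5, minbucket = 1, cp = 0))
        cat(as.character(fit$frame$var[1]), "\n")
        cat(sprintf("%.15g", fit$splits[1, "index"]), "\n")
    """)
    try:
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
    except (FileNotFoundError, subprocess.TimeoutExpired):
        pytest.skip("Rscript unavailable")
    lines = [l.strip() for l in out.stdout.strip().splitlines() if l.strip()]
    mine = fit_cart(table, TreeFitParams(minsplit=5), features=("f0", "f1"))
    assert lines[0] == mine.feature
    assert float(lines[1]) == pytest.approx(mine.threshold, abs=1e-9)
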