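import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dietscreen import cart
from dietscreen.cart import GrowthParams, gini


# ---------------------------------------------------------------------------
# Independent split-search oracle: plain nested loops, no shared code paths
# with dietscreen.cart.


def oracle_best_split(X, y, min_leaf=1):
    """Exhaustive enumeration over features x midpoint thresholds.

    Ties resolve to the lowest feature index, then the lowest threshold.
    Returns (feature, threshold, weighted_decrease) or None.
    """
    n = len(y)

    def _gini_counts(labels):
        n0 = int(np.sum(labels == 0))
        n1 = len(labels) - n0
        if n0 + n1 == 0:
            return 0.0
        p0, p1 = n0 / (n0 + n1), n1 / (n0 + n1)
        return 1.0 - p0 * p0 - p1 * p1

    parent = _gini_counts(y)
    best = None
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2.0
            left = X[:, j] < thr
            nl, nr = int(left.sum()), int((~left).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            dec = (
                parent
                - nl / n * _gini_counts(y[left])
                - nr / n * _gini_counts(y[~left])
            )
            if dec <= 1e-12:
                continue
            if best is None or dec > best[2] + 1e-12:
                best = (j, thr, dec)
    return best


def random_dataset(rng, n=None, p=None):
    n = n or int(rng.integers(20, 120))
    p = p or int(rng.integers(1, 6))
    # mix continuous and coarsely-discretized columns to exercise ties
    X = rng.normal(size=(n, p))
    for j in range(p):
        if rng.random() < 0.5:
            X[:, j] = np.round(X[:, j], 1)
    beta = rng.normal(size=p)
    logits = X @ beta + rng.normal(scale=1.0, size=n)
    y = (logits > np.median(logits)).astype(np.int8)
    if y.min() == y.max():  # force both classes
        y[0] = 1 - y[0]
    return X, y


# ---------------------------------------------------------------------------


def test_gini_examples():
    assert gini([5, 5]) == pytest.approx(0.5)
    assert gini([10, 0]) == pytest.approx(0.0)
    assert gini([3, 1]) == pytest.approx(0.375)
    with pytest.raises(ValueError):
        gini([0, 0])
    with pytest.raises(ValueError):
        gini([-1, 2])


def test_best_split_worked_example():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array([0, 0, 1, 1], dtype=np.int8)
    split = cart.best_split(X, y, GrowthParams(min_leaf_size=1))
    assert split.feature == 0
    assert split.threshold == pytest.approx(2.5)
    assert split.decrease == pytest.approx(0.5)


def test_best_split_pure_node_returns_none():
    X = np.array([[1.0], [2.0], [3.0]])
    y = np.zeros(3, dtype=np.int8)
    assert cart.best_split(X, y, GrowthParams(min_leaf_size=1)) is None


def test_best_split_feature_tie_breaks_to_lower_index():
    X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
    y = np.array([0, 0, 1, 1], dtype=np.int8)
    split = cart.best_split(X, y, GrowthParams(min_leaf_size=1))
    assert split.feature == 0


def test_best_split_agrees_with_oracle_small_batch():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        X, y = random_dataset(rng)
        ours = cart.best_split(X, y, GrowthParams(min_leaf_size=1))
        ref = oracle_best_split(X, y, min_leaf=1)
        if ref is None:
            assert ours is None
            continue
        assert ours.decrease == pytest.approx(ref[2], abs=1e-9)
        assert ours.feature == ref[0]
        assert ours.threshold == pytest.approx(ref[1], abs=1e-9)


def test_best_split_agrees_with_sklearn_stump():
    """Cross-check the split search against an established implementation."""
    sklearn_tree = pytest.importorskip("sklearn.tree")
    rng = np.random.default_rng(99)
    for _ in range(5):
        X, y = random_dataset(rng, n=80, p=4)
        ours = cart.best_split(X, y, GrowthParams(min_leaf_size=1))
        clf = sklearn_tree.DecisionTreeClassifier(max_depth=1, random_state=0)
        clf.fit(X, y)
        j = int(clf.tree_.feature[0])
        thr = float(clf.tree_.threshold[0])
        left = X[:, j] < thr  # sklearn routes <= left; midpoints make it equal
        n, nl, nr = len(y), int(left.sum()), int((~left).sum())
        their_dec = (
            gini(np.bincount(y, minlength=2))
            - nl / n * gini(np.bincount(y[left], minlength=2))
            - nr / n * gini(np.bincount(y[~left], minlength=2))
        )
        assert ours.decrease == pytest.approx(their_dec, abs=1e-9)


def test_grow_separable_data_single_split():
    X = np.array([[0.1], [0.2], [0.3], [1.1], [1.2], [1.3]])
    y = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
    tree = cart.grow_tree(X, y, ["x"], GrowthParams(min_node_size=2, min_leaf_size=1))
    assert tree.depth == 1
    assert tree.n_leaves == 2
    pred, _ = cart.predict(tree, X)
    assert (pred == np.array(["low"] * 3 + ["high"] * 3)).all()


def test_single_class_input_gives_root_leaf():
    X = np.random.default_rng(0).normal(size=(30, 3))
    y = np.zeros(30, dtype=np.int8)
    tree = cart.grow_tree(X, y, list("abc"))
    assert tree.root.is_leaf
    assert tree.root.prediction == "low"


def test_leaf_counts_partition_training_rows():
    rng = np.random.default_rng(5)
    X, y = random_dataset(rng, n=200, p=4)
    tree = cart.grow_tree(X, y, list("abcd"), GrowthParams(min_node_size=10, min_leaf_size=3))
    leaves = tree.leaves()
    assert sum(leaf.n for leaf in leaves) == 200
    assert sum(leaf.counts[0] for leaf in leaves) == int(np.sum(y == 0))
    # children counts sum to parents throughout
    for node in tree.internal_nodes():
        assert node.left.n + node.right.n == node.n


def test_max_depth_respected():
    rng = np.random.default_rng(8)
    X, y = random_dataset(rng, n=300, p=5)
    tree = cart.grow_tree(
        X, y, list("abcde"), GrowthParams(min_node_size=4, min_leaf_size=1, max_depth=3)
    )
    assert tree.depth <= 3


def _is_subtree(big, small):
    """Is `small` obtainable from `big` by collapsing internal nodes?"""
    if small.is_leaf:
        return small.counts == big.counts
    if big.is_leaf:
        return False
    return (
        big.feature == small.feature
        and big.threshold == small.threshold
        and _is_subtree(big.left, small.left)
        and _is_subtree(big.right, small.right)
    )


def test_prune_identity_and_full_collapse():
    rng = np.random.default_rng(12)
    X, y = random_dataset(rng, n=150, p=3)
    tree = cart.grow_tree(X, y, list("abc"), GrowthParams(min_node_size=10, min_leaf_size=3))
    unchanged = cart.cost_complexity_prune(tree, 0.0)
    assert _is_subtree(tree.root, unchanged.root)
    assert unchanged.n_leaves == tree.n_leaves
    stump = cart.cost_complexity_prune(tree, np.inf)
    assert stump.root.is_leaf


def test_prune_nestedness_and_monotonicity():
    rng = np.random.default_rng(31)
    for _ in range(10):
        X, y = random_dataset(rng, n=150, p=4)
        tree = cart.grow_tree(
            X, y, list("abcd"), GrowthParams(min_node_size=8, min_leaf_size=2)
        )
        cps = cart.cp_candidates(tree) + [np.inf]
        pruned = [cart.cost_complexity_prune(tree, cp) for cp in cps]
        errors = [
            np.mean(cart.predict(t, X)[0] != np.where(y == 0, "low", "high"))
            for t in pruned
        ]
        for smaller, larger in zip(pruned, pruned[1:]):
            assert _is_subtree(smaller.root, larger.root)
        assert all(a <= b + 1e-12 for a, b in zip(errors, errors[1:]))


def test_select_cp_deterministic():
    rng = np.random.default_rng(77)
    X, y = random_dataset(rng, n=200, p=4)
    a = cart.select_cp_monte_carlo(X, y, list("abcd"), seed=5)
    b = cart.select_cp_monte_carlo(X, y, list("abcd"), seed=5)
    assert a == b
    c = cart.select_cp_monte_carlo(X, y, list("abcd"), seed=6)
    assert [r["cp"] for r in c[1]] == [r["cp"] for r in a[1]]  # same grid


def test_select_cp_kfold_mode_runs():
    rng = np.random.default_rng(78)
    X, y = random_dataset(rng, n=150, p=3)
    cp, record = cart.select_cp_monte_carlo(X, y, list("abc"), seed=0, method="kfold")
    assert cp in [r["cp"] for r in record]


def test_predict_boundary_goes_right():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0, 0, 1, 1], dtype=np.int8)
    tree = cart.grow_tree(X, y, ["x"], GrowthParams(min_node_size=2, min_leaf_size=1))
    thr = tree.root.threshold
    cls, p_low = cart.predict(tree, {"x": thr})
    assert cls == "high"  # value == threshold routes to the ">=" branch
    cls2, _ = cart.predict(tree, {"x": thr - 1e-9})
    assert cls2 == "low"


def test_batch_predict_matches_rowwise(fitted_tree, demo_catalog, small_cohort):
    predictors = cart.build_predictor_matrix(
        small_cohort.cohort.head(30), demo_catalog
    )
    batch_cls, batch_p = cart.predict(fitted_tree, predictors)
    for i, (_, row) in enumerate(predictors.iterrows()):
        cls, p = cart.predict(fitted_tree, row.to_dict())
        assert cls == batch_cls[i]
        assert p == pytest.approx(batch_p[i])


def test_predict_missing_predictor_named():
    X = np.array([[0.0], [1.0], [0.0], [1.0]])
    y = np.array([0, 1, 0, 1], dtype=np.int8)
    tree = cart.grow_tree(X, y, ["veggies"], GrowthParams(min_node_size=2, min_leaf_size=1))
    with pytest.raises(cart.TreeError, match="veggies"):
        cart.predict(tree, {"other": 1.0})


def test_root_only_tree_predicts_majority():
    X = np.zeros((10, 2))
    y = np.array([0] * 7 + [1] * 3, dtype=np.int8)
    tree = cart.grow_tree(X, y, ["a", "b"])
    cls, p_low = cart.predict(tree, {"a": 5.0, "b": -3.0})
    assert cls == "low"
    assert p_low == pytest.approx(0.7)


def test_leaf_tie_breaks_to_low():
    node = cart.TreeNode((5, 5))
    assert node.prediction == "low"


def test_serialization_round_trip(fitted_tree, tmp_path):
    path = tmp_path / "tree.json"
    cart.save_tree(fitted_tree, path)
    loaded = cart.load_tree(path)
    assert loaded.predictor_ids == fitted_tree.predictor_ids
    assert _is_subtree(loaded.root, fitted_tree.root)
    assert _is_subtree(fitted_tree.root, loaded.root)
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 3, size=(50, len(fitted_tree.predictor_ids)))
    orig_cls, orig_p = cart.predict(fitted_tree, X)
    new_cls, new_p = cart.predict(loaded, X)
    assert (orig_cls == new_cls).all()
    assert orig_p == pytest.approx(new_p)


def test_tree_schema_version_checked(fitted_tree):
    data = cart.tree_to_dict(fitted_tree)
    data["schema_version"] = 99
    with pytest.raises(cart.TreeError, match="schema_version"):
        cart.tree_from_dict(data)


def test_build_predictor_matrix_layout(demo_catalog, small_cohort):
    pm = cart.build_predictor_matrix(small_cohort.cohort, demo_catalog)
    assert "other_foods" not in pm.columns  # excluded item
    assert set(demo_catalog.groups) <= set(pm.columns)
    assert {"age", "sex"} <= set(pm.columns)
    assert set(np.unique(pm["sex"])) <= {0.0, 1.0}
    # group columns equal the member sums
    members = demo_catalog.groups["processed_meat"]
    expected = small_cohort.cohort[list(members)].sum(axis=1)
    assert pm["processed_meat"].to_numpy() == pytest.approx(expected.to_numpy())
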