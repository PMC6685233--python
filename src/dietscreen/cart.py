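"""Binary classification trees (CART), written from first principles.

Greedy recursive partitioning on Gini impurity with exhaustive search over
axis-aligned thresholds, weakest-link cost-complexity pruning, and Monte
Carlo cross-validation for choosing the complexity parameter. Predictors
are continuous (item and group intakes in servings/day, age in years) or
binary-encoded (sex: 0 = female, 1 = male, split at 0.5). The two classes
are "low" and "high" diet quality; ties at a leaf resolve to "low", the
screening-conservative choice.

Split convention: rows with value < threshold go left, value >= threshold
go right. Tie-breaks in the split search are deterministic: lowest
predictor registry index first, then lowest threshold.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("low", "high")
TREE_SCHEMA_VERSION = 1

_EPS = 1e-12


class TreeError(ValueError):
    """Raised for invalid tree inputs (missing predictors, bad data)."""


@dataclass
class GrowthParams:
    min_node_size: int = 20  # smallest node the learner will try to split
    min_leaf_size: int = 7  # smallest admissible child
    max_depth: int = 6  # longest question pathway
    criterion: str = "gini"  # "gini" | "entropy"


def gini(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_k^2); in [0, 0.5] for two classes."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("class counts must not all be zero")
    p = counts / n
    return float(1.0 - np.sum(p * p))


def entropy(class_counts: Sequence[float]) -> float:
    counts = np.asarray(class_counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("class counts must not all be zero")
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


_IMPURITY = {"gini": gini, "entropy": entropy}


class TreeNode:
    """One node. Internal nodes carry (feature, threshold); every node
    carries its training class counts, from which leaf predictions and
    class probabilities derive."""

    __slots__ = ("feature", "threshold", "left", "right", "counts")

    def __init__(self, counts, feature=None, threshold=None, left=None, right=None):
        self.counts = (int(counts[0]), int(counts[1]))  # (n_low, n_high)
        self.feature = feature  # predictor registry index, None for leaf
        self.threshold = threshold
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return self.counts[0] + self.counts[1]

    @property
    def prediction(self) -> str:
        # tie -> "low": screening errs toward flagging poor diets
        return CLASSES[0] if self.counts[0] >= self.counts[1] else CLASSES[1]

    @property
    def p_low(self) -> float:
        return self.counts[0] / self.n

    def collapse(self) -> None:
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None


@dataclass
class Tree:
    root: TreeNode
    predictor_ids: tuple[str, ...]
    params: GrowthParams
    seed: int | None = None
    cv_record: list[dict] | None = None
    cp: float | None = None

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.right, node.left])
        return out

    @property
    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def split_features(self) -> set[str]:
        """Predictor ids used by at least one split."""
        return {self.predictor_ids[nd.feature] for nd in self.internal_nodes()}


@dataclass(frozen=True)
class Split:
    feature: int
    threshold: float
    decrease: float  # n-weighted impurity decrease at the node


# ---------------------------------------------------------------------------
# Split search


def _best_split_for_feature(
    x: np.ndarray, y: np.ndarray, min_leaf: int, impurity
) -> tuple[float, float] | None:
    """Best (threshold, weighted decrease) for one feature, or None."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    n = x.size
    boundaries = np.nonzero(np.diff(xs) > 0)[0]  # split after index i
    if boundaries.size == 0:
        return None
    n_left = boundaries + 1
    n_right = n - n_left
    valid = (n_left >= min_leaf) & (n_right >= min_leaf)
    if not valid.any():
        return None
    boundaries = boundaries[valid]
    n_left = n_left[valid]
    n_right = n_right[valid]
    cum_high = np.cumsum(ys)
    left_high = cum_high[boundaries]
    left_low = n_left - left_high
    right_high = cum_high[-1] - left_high
    right_low = n_right - right_high
    if impurity is gini:
        gl = 1.0 - (left_low / n_left) ** 2 - (left_high / n_left) ** 2
        gr = 1.0 - (right_low / n_right) ** 2 - (right_high / n_right) ** 2
        parent = gini([n - cum_high[-1], cum_high[-1]])
    else:
        def _h(a, b):
            tot = a + b
            pa = np.where(a > 0, a / tot, 1.0)
            pb = np.where(b > 0, b / tot, 1.0)
            return -(
                np.where(a > 0, a / tot * np.log2(pa), 0.0)
                + np.where(b > 0, b / tot * np.log2(pb), 0.0)
            )
        gl = _h(left_low, left_high)
        gr = _h(right_low, right_high)
        parent = entropy([n - cum_high[-1], cum_high[-1]])
    decrease = parent - (n_left / n) * gl - (n_right / n) * gr
    # ties within 1e-12 resolve to the lowest threshold (xs is sorted)
    best = int(np.flatnonzero(decrease >= decrease.max() - _EPS)[0])
    thr = 0.5 * (xs[boundaries[best]] + xs[boundaries[best] + 1])
    return float(thr), float(decrease[best])


def best_split(
    X: np.ndarray, y: np.ndarray, params: GrowthParams | None = None
) -> Split | None:
    """Exhaustive best split of one node, or None when no admissible split
    yields a positive impurity decrease."""
    params = params or GrowthParams()
    impurity = _IMPURITY[params.criterion]
    best: Split | None = None
    for j in range(X.shape[1]):
        found = _best_split_for_feature(X[:, j], y, params.min_leaf_size, impurity)
        if found is None:
            continue
        thr, dec = found
        if dec <= _EPS:
            continue
        if best is None or dec > best.decrease + _EPS:
            best = Split(feature=j, threshold=thr, decrease=dec)
    return best


# ---------------------------------------------------------------------------
# Growing


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    predictor_ids: Sequence[str],
    params: GrowthParams | None = None,
) -> Tree:
    """Grow a full tree by recursive partitioning.

    ``X`` is (n, p) float; ``y`` holds 0 (low) / 1 (high). Stops at pure
    nodes, nodes below ``min_node_size``, ``max_depth``, or when no split
    with positive impurity decrease and admissible child sizes exists.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TreeError("X must be (n, p) aligned with y")
    if np.isnan(X).any():
        raise TreeError("predictor matrix contains missing values")
    if len(predictor_ids) != X.shape[1]:
        raise TreeError("predictor_ids must match the number of columns")
    params = params or GrowthParams()

    def _grow(rows: np.ndarray, depth: int) -> TreeNode:
        ysub = y[rows]
        counts = (int(np.sum(ysub == 0)), int(np.sum(ysub == 1)))
        node = TreeNode(counts)
        if (
            counts[0] == 0
            or counts[1] == 0
            or node.n < params.min_node_size
            or depth >= params.max_depth
        ):
            return node
        split = best_split(X[rows], ysub, params)
        if split is None:
            return node
        node.feature = split.feature
        node.threshold = split.threshold
        go_left = X[rows, split.feature] < split.threshold
        node.left = _grow(rows[go_left], depth + 1)
        node.right = _grow(rows[~go_left], depth + 1)
        return node

    root = _grow(np.arange(X.shape[0]), 0)
    return Tree(root=root, predictor_ids=tuple(predictor_ids), params=params)


# ---------------------------------------------------------------------------
# Pruning


def _node_miss(node: TreeNode) -> int:
    """Training misclassifications if this node were a leaf."""
    return node.n - max(node.counts)


def _subtree_stats(node: TreeNode) -> tuple[int, int]:
    """(misclassifications over leaves, number of leaves) below ``node``."""
    if node.is_leaf:
        return _node_miss(node), 1
    ml, ll = _subtree_stats(node.left)
    mr, lr = _subtree_stats(node.right)
    return ml + mr, ll + lr


def _weakest_link(root: TreeNode) -> tuple[TreeNode, float] | None:
    """Internal node with the smallest per-leaf misclassification
    improvement g(t); ties resolve to the deepest, leftmost node."""
    best: tuple[TreeNode, float] | None = None

    def _visit(node: TreeNode) -> None:
        nonlocal best
        if node.is_leaf:
            return
        _visit(node.left)
        _visit(node.right)
        miss_sub, n_leaves = _subtree_stats(node)
        g = (_node_miss(node) - miss_sub) / (n_leaves - 1)
        if best is None or g < best[1] - _EPS:
            best = (node, g)

    _visit(root)
    return best


def cost_complexity_prune(tree: Tree, cp: float) -> Tree:
    """Weakest-link pruning: collapse internal nodes until every remaining
    split improves training misclassification by at least ``cp * n_root``
    per leaf it adds. Returns a new tree; larger ``cp`` gives a nested
    subtree of any smaller ``cp``'s result."""
    pruned = copy.deepcopy(tree)
    pruned.cp = float(cp)
    threshold = cp * pruned.root.n
    while True:
        weakest = _weakest_link(pruned.root)
        if weakest is None:
            break
        node, g = weakest
        if g < threshold - _EPS or (g <= threshold and not np.isfinite(threshold)):
            node.collapse()
        else:
            break
    return pruned


def cp_candidates(tree: Tree) -> list[float]:
    """Candidate complexity parameters from the grown tree's weakest-link
    sequence (geometric midpoints between consecutive critical values)."""
    scratch = copy.deepcopy(tree.root)
    n_root = scratch.n
    alphas: list[float] = []
    while True:
        weakest = _weakest_link(scratch)
        if weakest is None:
            break
        node, g = weakest
        alphas.append(g / n_root)
        node.collapse()
    alphas = sorted(set(alphas))
    cands = [0.0]
    for a, b in zip(alphas, alphas[1:]):
        cands.append(float(np.sqrt(a * b)) if a > 0 else b / 2.0)
    if alphas:
        top = alphas[-1]
        cands.append(top * 2.0 if top > 0 else 0.001)
    return sorted(set(cands))


# ---------------------------------------------------------------------------
# Cross-validation


def _stratified_holdout(
    y: np.ndarray, holdout_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_hold = max(1, int(round(holdout_fraction * idx.size)))
        test_idx.append(idx[:n_hold])
        train_idx.append(idx[n_hold:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _stratified_kfold(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].append(chunk)
    out = []
    for f in range(k):
        test = np.concatenate(folds[f])
        train = np.concatenate(
            [np.concatenate(folds[g]) for g in range(k) if g != f]
        )
        out.append((train, test))
    return out


def _misclassification(tree: Tree, X: np.ndarray, y: np.ndarray) -> float:
    pred = _predict_indices(tree.root, X)
    return float(np.mean(pred != y))


def select_cp_monte_carlo(
    X: np.ndarray,
    y: np.ndarray,
    predictor_ids: Sequence[str],
    params: GrowthParams | None = None,
    n_repeats: int = 10,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    method: str = "mc",
    one_se: bool = False,
) -> tuple[float, list[dict]]:
    """Choose the complexity parameter by repeated random stratified
    holdouts ("Monte Carlo" CV; ``method="kfold"`` gives standard
    stratified 10-fold instead).

    Candidate values come from the tree grown on the full data. For each
    resample a tree is grown on the training part and evaluated on the
    holdout at every candidate. Returns the candidate minimizing mean
    holdout misclassification (ties -> largest, i.e. simplest; with
    ``one_se`` the largest candidate within one standard error of the
    minimum) together with the per-candidate cv record.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TreeError("cross-validation requires both classes present")
    params = params or GrowthParams()
    rng = np.random.default_rng(seed)
    full = grow_tree(X, y, predictor_ids, params)
    cands = cp_candidates(full)
    if method == "kfold":
        splits = _stratified_kfold(y, 10, rng)
    elif method == "mc":
        splits = []
        for _ in range(n_repeats):
            for _attempt in range(100):
                train, test = _stratified_holdout(y, holdout_fraction, rng)
                if len(np.unique(y[train])) == 2:
                    break
            else:
                raise TreeError(
                    "could not build a training split containing both classes"
                )
            splits.append((train, test))
    else:
        raise ValueError("method must be 'mc' or 'kfold'")

    errs = np.empty((len(splits), len(cands)))
    for r, (train, test) in enumerate(splits):
        grown = grow_tree(X[train], y[train], predictor_ids, params)
        for c, cp in enumerate(cands):
            errs[r, c] = _misclassification(
                cost_complexity_prune(grown, cp), X[test], y[test]
            )
    mean = errs.mean(axis=0)
    sd = errs.std(axis=0, ddof=1) if len(splits) > 1 else np.zeros(len(cands))
    best_idx = int(np.argmin(mean))
    if one_se:
        if method == "mc":
            # Nadeau-Bengio variance correction for repeated random
            # holdouts: overlapping training sets make the naive 1/R
            # factor an underestimate
            var_factor = 1.0 / len(splits) + holdout_fraction / (
                1.0 - holdout_fraction
            )
        else:
            var_factor = 1.0 / len(splits)
        limit = mean[best_idx] + sd[best_idx] * np.sqrt(var_factor)
        eligible = np.flatnonzero(mean <= limit + _EPS)
    else:
        eligible = np.flatnonzero(mean <= mean[best_idx] + _EPS)
    cp_star = float(cands[int(eligible.max())])  # ties -> simplest tree
    record = [
        {"cp": float(c), "mean_misclassification": float(m), "sd": float(s)}
        for c, m, s in zip(cands, mean, sd)
    ]
    return cp_star, record


# ---------------------------------------------------------------------------
# Prediction


def _predict_indices(root: TreeNode, X: np.ndarray) -> np.ndarray:
    """Vector of 0/1 class indices by recursive mask routing."""
    out = np.empty(X.shape[0], dtype=np.int8)

    def _route(node: TreeNode, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = 0 if node.prediction == CLASSES[0] else 1
            return
        left = X[rows, node.feature] < node.threshold
        _route(node.left, rows[left])
        _route(node.right, rows[~left])

    _route(root, np.arange(X.shape[0]))
    return out


def _p_low_vector(root: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=float)

    def _route(node: TreeNode, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = node.p_low
            return
        left = X[rows, node.feature] < node.threshold
        _route(node.left, rows[left])
        _route(node.right, rows[~left])

    _route(root, np.arange(X.shape[0]))
    return out


def _matrix_from(data, predictor_ids: Sequence[str]) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        missing = [p for p in predictor_ids if p not in data.columns]
        if missing:
            raise TreeError(f"missing predictor column(s): {missing}")
        X = data.loc[:, list(predictor_ids)].to_numpy(dtype=float)
    elif isinstance(data, Mapping):
        missing = [p for p in predictor_ids if p not in data]
        if missing:
            raise TreeError(f"missing predictor(s): {missing}")
        X = np.asarray([[float(data[p]) for p in predictor_ids]])
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(predictor_ids):
            raise TreeError("predictor vector length mismatch")
    if np.isnan(X).any():
        raise TreeError("predictors contain missing values")
    return X


def predict(tree: Tree, data) -> tuple:
    """Route respondents through the tree.

    ``data`` may be a mapping (one respondent: returns ``(class, p_low)``),
    a DataFrame or a 2-D array (returns aligned arrays). Values equal to a
    threshold go right (the ">=" branch).
    """
    single = isinstance(data, Mapping) or (
        isinstance(data, np.ndarray) and np.ndim(data) == 1
    )
    X = _matrix_from(data, tree.predictor_ids)
    idx = _predict_indices(tree.root, X)
    p_low = _p_low_vector(tree.root, X)
    classes = np.asarray(CLASSES)[idx]
    if single:
        return str(classes[0]), float(p_low[0])
    return classes, p_low


# ---------------------------------------------------------------------------
# Predictor matrix construction


def build_predictor_matrix(cohort: pd.DataFrame, catalog) -> pd.DataFrame:
    """Assemble the predictor table: non-excluded item intakes, food-group
    intakes, age, and sex encoded 0 = female / 1 = male."""
    from .ffq import cohort_group_intakes

    out = cohort.loc[:, list(catalog.predictor_item_ids)].copy()
    groups = cohort_group_intakes(cohort, catalog)
    for gid in groups.columns:
        out[gid] = groups[gid]
    out["age"] = cohort["age"].astype(float)
    out["sex"] = (cohort["sex"] == "male").astype(float)
    if out.isna().any().any():
        raise TreeError("predictor matrix contains missing values")
    return out


def fit_classification_tree(
    predictors: pd.DataFrame,
    labels: Sequence[str],
    params: GrowthParams | None = None,
    seed: int = 0,
    cv_method: str = "mc",
    n_repeats: int = 10,
    holdout_fraction: float = 0.1,
    one_se: bool = False,
) -> Tree:
    """Grow on the full data, select cp by cross-validation, and prune."""
    params = params or GrowthParams()
    y = _encode_labels(labels)
    X = predictors.to_numpy(dtype=float)
    ids = tuple(predictors.columns)
    cp_star, record = select_cp_monte_carlo(
        X,
        y,
        ids,
        params,
        n_repeats=n_repeats,
        holdout_fraction=holdout_fraction,
        seed=seed,
        method=cv_method,
        one_se=one_se,
    )
    full = grow_tree(X, y, ids, params)
    tree = cost_complexity_prune(full, cp_star)
    tree.seed = seed
    tree.cv_record = record
    tree.cp = cp_star
    return tree


def _encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    bad = set(np.unique(arr)) - set(CLASSES)
    if bad:
        raise TreeError(f"labels must be in {CLASSES}; got {sorted(bad)}")
    return (arr == CLASSES[1]).astype(np.int8)


# ---------------------------------------------------------------------------
# Serialization


def _node_to_dict(node: TreeNode) -> dict:
    d = {"counts": list(node.counts)}
    if node.is_leaf:
        d["type"] = "leaf"
        d["prediction"] = node.prediction
        d["p_low"] = node.p_low
    else:
        d["type"] = "split"
        d["feature"] = int(node.feature)
        d["threshold"] = float(node.threshold)
        d["left"] = _node_to_dict(node.left)
        d["right"] = _node_to_dict(node.right)
    return d


def _node_from_dict(d: Mapping) -> TreeNode:
    if d["type"] == "leaf":
        return TreeNode(d["counts"])
    return TreeNode(
        d["counts"],
        feature=int(d["feature"]),
        threshold=float(d["threshold"]),
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def tree_to_dict(tree: Tree) -> dict:
    return {
        "schema_version": TREE_SCHEMA_VERSION,
        "classes": list(CLASSES),
        "predictor_ids": list(tree.predictor_ids),
        "params": asdict(tree.params),
        "seed": tree.seed,
        "cp": tree.cp,
        "cv_record": tree.cv_record,
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(data: Mapping) -> Tree:
    if data.get("schema_version") != TREE_SCHEMA_VERSION:
        raise TreeError(
            f"unsupported tree schema_version {data.get('schema_version')!r}"
        )
    return Tree(
        root=_node_from_dict(data["root"]),
        predictor_ids=tuple(data["predictor_ids"]),
        params=GrowthParams(**data["params"]),
        seed=data.get("seed"),
        cv_record=data.get("cv_record"),
        cp=data.get("cp"),
    )


def save_tree(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=2, sort_keys=True))


def load_tree(path: str | Path) -> Tree:
    return tree_from_dict(json.loads(Path(path).read_text()))
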