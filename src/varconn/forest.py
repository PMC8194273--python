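"""Bagged Gini decision trees with per-tree feature subsetting.

Each tree is grown greedily on a bootstrap resample of the rows using only
a fixed random subset of the columns (the whole tree sees the same subset
— not a fresh subset per split).  A node is split only while it holds at
least 2M samples and both children would keep at least M; the split
minimises the child-size-weighted Gini impurity, scanning thresholds at
midpoints between consecutive distinct sorted values, with deterministic
ties broken toward the lowest feature index and then the lowest
threshold.  Gini feature importance accumulates the node-fraction-
weighted impurity decrease of every split and is normalised to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ValidationError


def gini_impurity(class_fractions: Sequence[float]) -> float:
    """Two-class Gini impurity G = p_A(1-p_A) + p_B(1-p_B).

    The fractions must be in [0, 1] and sum to 1 (within 1e-9).
    """
    fractions = np.asarray(class_fractions, dtype=float)
    if np.any(fractions < -1e-12) or np.any(fractions > 1 + 1e-12):
        raise ValidationError("class fractions must lie in [0, 1]")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError("class fractions must sum to 1")
    return float(np.sum(fractions * (1.0 - fractions)))


@dataclass(frozen=True)
class Split:
    feature: int          # global column index
    threshold: float
    decrease: float       # parent Gini - weighted child Gini


def _gini_from_counts(n1: np.ndarray | float, n: np.ndarray | float):
    """Vectorised two-class Gini from class-1 counts n1 out of n."""
    p = np.asarray(n1, dtype=float) / np.asarray(n, dtype=float)
    return 2.0 * p * (1.0 - p)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidate_features: Sequence[int],
    min_leaf: int,
) -> Split | None:
    """Exhaustive best Gini split of a node, or None if no legal split.

    ``value <= threshold`` routes left.  Returns None when the node is
    pure, has fewer than ``2 * min_leaf`` samples, or no threshold leaves
    ``min_leaf`` samples on both sides.
    """
    n = y.size
    if n < 2 * min_leaf:
        return None
    n1_total = int(y.sum())
    parent = _gini_from_counts(n1_total, n)
    if parent == 0.0:
        return None

    best: Split | None = None
    eps = 1e-12
    for feat in candidate_features:
        vals = X[:, feat]
        order = np.argsort(vals, kind="stable")
        v = vals[order]
        y_sorted = y[order]
        # candidate cut after position i (0-based) iff v[i] < v[i+1]
        cuts = np.flatnonzero(v[:-1] < v[1:])
        if cuts.size == 0:
            continue
        n_left = cuts + 1
        ok = (n_left >= min_leaf) & (n - n_left >= min_leaf)
        cuts, n_left = cuts[ok], n_left[ok]
        if cuts.size == 0:
            continue
        cum1 = np.cumsum(y_sorted)
        left1 = cum1[cuts]
        right1 = n1_total - left1
        weighted = (
            n_left * _gini_from_counts(left1, n_left)
            + (n - n_left) * _gini_from_counts(right1, n - n_left)
        ) / n
        k = int(np.argmin(weighted))  # first minimum -> lowest threshold
        decrease = parent - float(weighted[k])
        if decrease <= eps:
            continue
        if best is None or decrease > best.decrease + eps:
            threshold = 0.5 * (v[cuts[k]] + v[cuts[k] + 1])
            best = Split(int(feat), float(threshold), decrease)
    return best


@dataclass
class _Node:
    # leaf: feature < 0, proba = class-1 fraction
    feature: int
    threshold: float
    proba: float
    left: "_Node | None" = None
    right: "_Node | None" = None


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    features: np.ndarray,
    min_leaf: int,
    n_total: int,
    importance: np.ndarray,
) -> _Node:
    y_node = y[rows]
    proba = float(y_node.mean()) if y_node.size else 0.5
    split = best_split(X[rows], y_node, features, min_leaf)
    if split is None:
        return _Node(-1, 0.0, proba)
    importance[split.feature] += (rows.size / n_total) * split.decrease
    go_left = X[rows, split.feature] <= split.threshold
    left = _grow(X, y, rows[go_left], features, min_leaf, n_total, importance)
    right = _grow(X, y, rows[~go_left], features, min_leaf, n_total, importance)
    return _Node(split.feature, split.threshold, proba, left, right)


def _predict_node(node: _Node, x: np.ndarray) -> float:
    while node.feature >= 0:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.proba


@dataclass
class _Tree:
    root: _Node
    features: np.ndarray  # the per-tree column subset (global indices)


class RandomForest:
    """Binary random-forest classifier with Gini feature importances.

    Parameters
    ----------
    n_trees : int
        Ensemble size T.
    min_leaf : int
        Minimum samples per leaf M; nodes with fewer than 2M samples are
        not split.
    feature_fraction : float
        Fraction P of columns drawn (without replacement) for each tree;
        the subset size is ``floor(P * n_features)``, at least 1.
    seed : int
        Seed for bootstrap resampling and feature subsetting.
    """

    def __init__(
        self,
        n_trees: int = 200,
        min_leaf: int = 10,
        feature_fraction: float = 0.025,
        seed: int = 0,
    ) -> None:
        if n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")
        if not (0 < feature_fraction <= 1):
            raise ValidationError("feature_fraction must be in (0, 1]")
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.feature_fraction = feature_fraction
        self.seed = seed
        self.trees_: list[_Tree] = []
        self.n_features_: int | None = None
        self.feature_importances_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValidationError("X must be 2-D with one label per row")
        if np.unique(y).size < 2:
            raise ValidationError("training labels contain a single class")
        n, d = X.shape
        subset_size = max(1, int(self.feature_fraction * d))
        rng = np.random.default_rng(self.seed)
        importance = np.zeros(d)
        self.trees_ = []
        for _ in range(self.n_trees):
            rows = rng.integers(0, n, size=n)  # bootstrap, same size
            features = np.sort(rng.choice(d, size=subset_size, replace=False))
            root = _grow(X, y, rows, features, self.min_leaf, n, importance)
            self.trees_.append(_Tree(root, features))
        total = importance.sum()
        if total > 0:
            importance = importance / total
        else:
            import warnings

            warnings.warn("no split occurred in any tree; importances are all zero")
        self.n_features_ = d
        self.feature_importances_ = importance
        return self

    @property
    def feature_subset_sizes_(self) -> list[int]:
        return [t.features.size for t in self.trees_]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees of the leaf class-1 fraction, per sample."""
        if not self.trees_:
            raise ValidationError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValidationError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model was trained with {self.n_features_}"
            )
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            for i, x in enumerate(X):
                out[i] += _predict_node(tree.root, x)
        return out / self.n_trees

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 200,
    min_leaf: int = 10,
    feature_fraction: float = 0.025,
    seed: int = 0,
) -> RandomForest:
    """Convenience constructor + fit (paper defaults T=200, M=10, P=2.5%)."""
    return RandomForest(n_trees, min_leaf, feature_fraction, seed).fit(X, y)


def gini_importance(model: RandomForest) -> np.ndarray:
    """Normalised (sum-to-1) Gini importances of a fitted forest."""
    if model.feature_importances_ is None:
        raise ValidationError("forest is not fitted")
    return model.feature_importances_
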