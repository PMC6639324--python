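"""Gain-ratio decision tree with pessimistic error-based pruning.

A scikit-learn-compatible classifier in the C4.5/C5.0 family: splits are
chosen to maximize the information gain ratio (gain / split information),
numeric features get binary threshold splits at midpoints between observed
values, declared-categorical features get multiway splits, and the grown tree
is pruned bottom-up by comparing pessimistic error estimates — the upper
confidence limit of the binomial error rate at confidence factor CF (default
0.25, the family's historical default).  Subtree raising is not implemented;
pruning only collapses subtrees to leaves.

Prediction scores are leaf class frequencies.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["GainRatioTreeClassifier", "pessimistic_error_rate", "gain_ratio"]

_EPS = 1e-12


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def gain_ratio(y, groups) -> tuple[float, float]:
    """(information gain, gain ratio) of partitioning labels ``y`` by ``groups``.

    ``groups`` assigns each sample an arbitrary branch identifier.  Exposed for
    auditability of the split criterion.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    classes, yc = np.unique(y, return_inverse=True)
    total = np.bincount(yc, minlength=classes.size).astype(float)
    h_total = _entropy(total)
    n = y.size
    cond = 0.0
    split_info_terms = []
    for g in np.unique(groups):
        sel = groups == g
        ng = int(sel.sum())
        cond += ng / n * _entropy(np.bincount(yc[sel], minlength=classes.size).astype(float))
        split_info_terms.append(ng / n)
    gain = h_total - cond
    si = _entropy(np.asarray(split_info_terms) * n)
    ratio = gain / si if si > _EPS else 0.0
    return float(gain), float(ratio)


def pessimistic_error_rate(errors: float, n: float, cf: float = 0.25) -> float:
    """Upper confidence limit of the binomial error rate (C4.5's U_CF(E, N))."""
    if n <= 0:
        return 0.0
    e = min(errors, n)
    if e >= n:
        return 1.0
    return float(stats.beta.ppf(1.0 - cf, e + 1.0, n - e))


class _Node:
    __slots__ = ("counts", "feature", "threshold", "children", "branch_values")

    def __init__(self, counts: np.ndarray):
        self.counts = counts
        self.feature: int | None = None
        self.threshold: float | None = None
        self.children: list["_Node"] | None = None
        self.branch_values: np.ndarray | None = None  # categorical branch keys

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def n_errors(self) -> float:
        return float(self.counts.sum() - self.counts.max())


class GainRatioTreeClassifier(ClassifierMixin, BaseEstimator):
    """C4.5-family decision tree (gain-ratio splits, pessimistic pruning).

    Parameters
    ----------
    cf : float
        Pruning confidence factor; smaller prunes harder.
    min_samples_leaf, min_samples_split : int
        Minimum samples in a child / to attempt a split.
    categorical_features : sequence of int, optional
        Column indices treated as categorical (multiway splits on the distinct
        values); all other columns are numeric with binary threshold splits.
    """

    def __init__(
        self,
        cf: float = 0.25,
        min_samples_leaf: int = 2,
        min_samples_split: int = 4,
        categorical_features=None,
    ):
        self.cf = cf
        self.min_samples_leaf = min_samples_leaf
        self.min_samples_split = min_samples_split
        self.categorical_features = categorical_features

    # -- growing -----------------------------------------------------------

    def _best_numeric_split(self, v: np.ndarray, yc: np.ndarray, n_classes: int):
        order = np.argsort(v, kind="mergesort")
        vs, ys = v[order], yc[order]
        n = v.size
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left = np.cumsum(onehot, axis=0)  # class counts among first i+1
        total = left[-1]
        cut = np.nonzero(np.diff(vs) > 0)[0]  # split after position i
        if cut.size == 0:
            return None
        n_l = cut + 1
        n_r = n - n_l
        keep = (n_l >= self.min_samples_leaf) & (n_r >= self.min_samples_leaf)
        cut = cut[keep]
        if cut.size == 0:
            return None
        n_l, n_r = n_l[keep], n_r[keep]
        lc = left[cut]
        rc = total[None, :] - lc
        h_total = _entropy(total)

        def _h_rows(c):
            s = c.sum(axis=1, keepdims=True)
            p = np.divide(c, s, out=np.zeros_like(c), where=s > 0)
            lg = np.log2(p, out=np.zeros_like(p), where=p > 0)
            return -(p * lg).sum(axis=1)

        gain = h_total - (n_l * _h_rows(lc) + n_r * _h_rows(rc)) / n
        fl, fr = n_l / n, n_r / n
        split_info = -(fl * np.log2(fl) + fr * np.log2(fr))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(split_info > _EPS, gain / split_info, 0.0)
        ok = gain > 1e-9
        if not ok.any():
            return None
        ratio = np.where(ok, ratio, -np.inf)
        k = int(np.argmax(ratio))
        thr = (vs[cut[k]] + vs[cut[k] + 1]) / 2.0
        return float(ratio[k]), float(thr)

    def _best_categorical_split(self, v: np.ndarray, yc: np.ndarray, n_classes: int):
        values = np.unique(v)
        if values.size < 2:
            return None
        sizes = np.array([(v == val).sum() for val in values])
        if sizes.min() < self.min_samples_leaf:
            return None
        g, ratio = gain_ratio(yc, v)
        if g <= 1e-9:
            return None
        return float(ratio), values

    def _grow(self, X: np.ndarray, yc: np.ndarray) -> _Node:
        counts = np.bincount(yc, minlength=self.n_classes_).astype(float)
        node = _Node(counts)
        n = yc.size
        if n < self.min_samples_split or (counts > 0).sum() < 2:
            return node
        cat = self._categorical_set_
        best = None  # (ratio, feature, kind, payload)
        for j in range(X.shape[1]):
            v = X[:, j]
            if j in cat:
                res = self._best_categorical_split(v, yc, self.n_classes_)
                if res is not None and (best is None or res[0] > best[0]):
                    best = (res[0], j, "cat", res[1])
            else:
                res = self._best_numeric_split(v, yc, self.n_classes_)
                if res is not None and (best is None or res[0] > best[0]):
                    best = (res[0], j, "num", res[1])
        if best is None:
            return node
        _, j, kind, payload = best
        node.feature = j
        if kind == "num":
            node.threshold = payload
            sel = X[:, j] <= payload
            node.children = [self._grow(X[sel], yc[sel]), self._grow(X[~sel], yc[~sel])]
        else:
            node.branch_values = payload
            node.children = []
            for val in payload:
                sel = X[:, j] == val
                node.children.append(self._grow(X[sel], yc[sel]))
        return node

    # -- pruning -----------------------------------------------------------

    def _pessimistic_errors(self, node: _Node) -> float:
        n = node.counts.sum()
        return n * pessimistic_error_rate(node.n_errors(), n, self.cf)

    def _prune(self, node: _Node) -> float:
        """Prune bottom-up; return the pessimistic error count of the result."""
        if node.is_leaf:
            return self._pessimistic_errors(node)
        subtree = sum(self._prune(child) for child in node.children)
        as_leaf = self._pessimistic_errors(node)
        if as_leaf <= subtree + 1e-9:
            node.children = None
            node.feature = None
            node.threshold = None
            node.branch_values = None
            return as_leaf
        return subtree

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        if self.classes_.size < 2:
            raise ValueError("GainRatioTreeClassifier requires at least 2 classes")
        self.n_classes_ = self.classes_.size
        yc = np.searchsorted(self.classes_, y)
        self._categorical_set_ = set(self.categorical_features or ())
        self.tree_ = self._grow(X, yc)
        self._prune(self.tree_)
        return self

    def _leaf(self, node: _Node, x: np.ndarray) -> _Node:
        while not node.is_leaf:
            j = node.feature
            if node.threshold is not None:
                node = node.children[0] if x[j] <= node.threshold else node.children[1]
            else:
                hits = np.nonzero(node.branch_values == x[j])[0]
                if hits.size == 0:
                    break  # unseen category: stop at this node
                node = node.children[int(hits[0])]
        return node

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, ensure_2d=True, dtype=np.float64, reset=False)
        out = np.empty((X.shape[0], self.n_classes_))
        for i, x in enumerate(X):
            counts = self._leaf(self.tree_, x).counts
            total = counts.sum()
            out[i] = counts / total if total > 0 else 1.0 / self.n_classes_
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def root_feature_(self) -> int | None:
        """Column index of the first (root) split, or None for a stump."""
        check_is_fitted(self)
        return self.tree_.feature

    def n_leaves(self) -> int:
        def _count(node: _Node) -> int:
            if node.is_leaf:
                return 1
            return sum(_count(c) for c in node.children)

        return _count(self.tree_)
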