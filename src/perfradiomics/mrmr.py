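"""Maximum-Relevance-Minimum-Redundancy (MRMR) feature ranking.

Features are discretized to three states by the classic mean +/- sigma rule,
mutual information is the plug-in estimate from the joint contingency table
(base 2), and ranking follows the greedy MID (difference) scheme: at each step
pick the unselected feature maximizing

    MI(feature; label) - mean over selected s of MI(feature; s)

Ties break by column order, so the ranking is deterministic.  ``MRMRSelector``
wraps the ranking as a scikit-learn feature selector usable in pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import FeatureTable

__all__ = [
    "SelectionResult",
    "discretize_feature",
    "mutual_information",
    "mrmr_rank",
    "sweep_sizes",
    "default_sweep_sizes",
    "MRMRSelector",
]


@dataclass(frozen=True)
class SelectionResult:
    ranked_features: list[str]
    scores: list[float]  # greedy MID objective at selection time
    relevance: list[float]  # MI(feature; label), bits, for the ranked features


def discretize_feature(x) -> np.ndarray:
    """Three-state symbols {-1, 0, +1} by thresholds mean +/- sigma.

    Sigma is the population standard deviation; a constant input maps to all
    zeros.  Positive-affine transforms of x give the identical symbol sequence.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("discretize_feature requires finite values")
    mu = x.mean()
    sigma = x.std()
    out = np.zeros(x.shape, dtype=np.int8)
    if sigma > 0:
        out[x < mu - sigma] = -1
        out[x > mu + sigma] = 1
    return out


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def mutual_information(a, b) -> float:
    """Plug-in mutual information (bits) between two symbol sequences."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("symbol sequences must be 1D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    counts = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    return _mi_from_counts(counts.astype(np.float64))


def _mi_columns(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI (bits) of each column of code matrix D (values 0..2) against codes y."""
    n, p = D.shape
    ky = int(y.max()) + 1 if y.size else 1
    out = np.empty(p)
    joint = D * ky + y[:, None]
    for j in range(p):
        counts = np.bincount(joint[:, j], minlength=3 * ky).reshape(3, ky)
        out[j] = _mi_from_counts(counts.astype(np.float64))
    return out


def _codes(X: np.ndarray) -> np.ndarray:
    """Discretize every column to codes {0,1,2} (= states -1,0,+1 shifted)."""
    D = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        D[:, j] = discretize_feature(X[:, j]) + 1
    return D


def mrmr_rank_matrix(X: np.ndarray, y: np.ndarray, k: int):
    """Greedy MID ranking on a raw matrix; returns (order, scores, relevance)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, p = X.shape
    if k < 1 or k > p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("mrmr_rank requires at least 2 classes")
    D = _codes(X)
    relevance = _mi_columns(D, y_codes)

    order: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for step in range(k):
        objective = relevance - (red_sum / step if step else 0.0)
        objective = np.where(remaining, objective, -np.inf)
        j = int(np.argmax(objective))  # first max = column-order tie-break
        order.append(j)
        scores.append(float(objective[j]))
        remaining[j] = False
        if step < k - 1:
            red_sum += _mi_columns(D, D[:, j])
    return order, scores, relevance


def mrmr_rank(table: FeatureTable, labels=None, k: int | None = None) -> SelectionResult:
    """Rank a FeatureTable's columns by greedy MRMR (MID objective)."""
    if labels is None:
        y = table.label_array()
    else:
        y = np.asarray([getattr(l, "value", l) for l in labels])
    if k is None:
        k = table.n_features
    order, scores, relevance = mrmr_rank_matrix(table.values, y, k)
    return SelectionResult(
        ranked_features=[table.feature_names[j] for j in order],
        scores=scores,
        relevance=[float(relevance[j]) for j in order],
    )


def default_sweep_sizes(n_features: int, stop: int = 20, step: int = 10) -> list[int]:
    """Descending featureset sizes: n_features, n_features-step, ..., stop."""
    if n_features < stop:
        raise ValueError(f"fewer than {stop} features available")
    return list(range(n_features, stop - 1, -step))


def sweep_sizes(table: FeatureTable, labels=None, sizes=None) -> dict[int, list[str]]:
    """Per-size candidate feature sets as nested prefixes of one greedy ranking."""
    if sizes is None:
        sizes = default_sweep_sizes(table.n_features)
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    bad = [s for s in sizes if s < 1 or s > table.n_features]
    if bad:
        raise ValueError(f"invalid featureset sizes: {bad}")
    result = mrmr_rank(table, labels, k=max(sizes))
    return {s: result.ranked_features[:s] for s in sizes}


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector backed by greedy MRMR ranking.

    Parameters
    ----------
    k : int
        Number of features to keep (the top-k of the greedy ranking).

    Attributes
    ----------
    ranking_ : ndarray of int
        Column indices in greedy selection order (length k).
    scores_ : ndarray of float
        MID objective value of each selected feature at selection time.
    relevance_ : ndarray of float
        MI(feature; label) in bits for every input column.
    """

    def __init__(self, k: int = 60):
        self.k = k

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=np.float64)
        y = np.asarray(y)
        order, scores, relevance = mrmr_rank_matrix(X, y, self.k)
        self.ranking_ = np.asarray(order)
        self.scores_ = np.asarray(scores)
        self.relevance_ = relevance
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.ranking_] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_
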