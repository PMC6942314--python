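"""Baseline classifiers over the aspect-score triple.

Three families, all selecting their free parameters on the training set by
maximizing the weighted average of per-class F-measures (WAF):

* **static combinations** — a single aspect score (BP / CC / MF) or the
  average (Avg) / maximum (Max) of the three, with the best classification
  threshold scanned on a 0.01 grid;
* **exhaustive grid search** — a weighted average of the three scores, with
  weights on a 0.1 grid and thresholds on a 0.05 grid, scoring a pair
  positive when the combined score strictly exceeds the threshold;
* **decision tree** — a default-parameter CART tree on the raw triple.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .gp import DegenerateTrainingError
from .similarity import FeatureTable

STATIC_KINDS = ("BP", "CC", "MF", "Avg", "Max")


def _waf_binary(y_true: np.ndarray, preds: np.ndarray) -> np.ndarray:
    """Support-weighted F-measure for 0/1 labels, vectorized over rows of
    ``preds`` (shape (..., n)).  Zero-division conventions: a class with no
    true or predicted members gets F = 0 and weight = its true support."""
    y = y_true.astype(float)
    n = y.size
    pos = y.sum()
    neg = n - pos
    p = preds.astype(float)
    tp1 = p @ y
    pred1 = p.sum(axis=-1)
    prec1 = np.divide(tp1, pred1, out=np.zeros_like(tp1), where=pred1 > 0)
    rec1 = tp1 / pos if pos > 0 else np.zeros_like(tp1)
    d1 = prec1 + rec1
    f1 = np.divide(2 * prec1 * rec1, d1, out=np.zeros_like(d1), where=d1 > 0)
    tp0 = (1 - p) @ (1 - y)
    pred0 = n - pred1
    prec0 = np.divide(tp0, pred0, out=np.zeros_like(tp0), where=pred0 > 0)
    rec0 = tp0 / neg if neg > 0 else np.zeros_like(tp0)
    d0 = prec0 + rec0
    f0 = np.divide(2 * prec0 * rec0, d0, out=np.zeros_like(d0), where=d0 > 0)
    return (f1 * pos + f0 * neg) / n


def combine_static(features, kind: str, aspects: tuple[str, ...] = ("BP", "CC", "MF")):
    """Collapse the aspect-score triple(s) into one score.

    ``features`` may be a single triple or an (n, 3) array; aspect kinds
    pick the matching column, ``Avg`` the arithmetic mean and ``Max`` the
    maximum.
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if kind == "Avg":
        out = X.mean(axis=1)
    elif kind == "Max":
        out = X.max(axis=1)
    elif kind in aspects:
        out = X[:, aspects.index(kind)]
    else:
        raise ValueError(f"unknown static combination kind {kind!r}")
    return float(out[0]) if single else out


def fit_threshold(
    scores, labels, step: float = 0.01
) -> tuple[float, float]:
    """Scan thresholds 0.00..1.00 and return (threshold, training WAF).

    Classification rule: score > threshold => class 1.  On ties the
    smallest maximizing threshold wins.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("labels contain a single class")
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    preds = scores[None, :] > thresholds[:, None]
    wafs = _waf_binary(y, preds)
    i = int(np.argmax(wafs))  # argmax returns the first (smallest) maximizer
    return float(thresholds[i]), float(wafs[i])


@dataclass
class GridSolution:
    """Winning point of the exhaustive weighted-average search."""

    weights: tuple[float, float, float]
    threshold: float
    train_waf: float


def grid_search(
    train: FeatureTable | tuple,
    weight_step: float = 0.1,
    threshold_step: float = 0.05,
) -> GridSolution:
    """Exhaustive search over weight triples and thresholds.

    Weights range over 0..1 on the ``weight_step`` grid (the all-zero
    triple is excluded — the weighted average is undefined there);
    thresholds over 0..1 on the ``threshold_step`` grid.  The combined
    score is the weight-normalized average sum(w*s)/sum(w); a pair is
    positive when it strictly exceeds the threshold.  Ties resolve to the
    first candidate in lexicographic (w_BP, w_CC, w_MF, threshold) order.
    """
    if isinstance(train, FeatureTable):
        X, y = train.X, train.y
    else:
        X, y = train
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty training table")
    n_weights = int(round(1.0 / weight_step)) + 1
    levels = np.round(np.arange(n_weights) * weight_step, 10)
    triples = [
        w for w in itertools.product(levels, repeat=X.shape[1]) if any(w)
    ]
    W = np.asarray(triples, dtype=float)
    combined = (W @ X.T) / W.sum(axis=1, keepdims=True)
    n_thr = int(round(1.0 / threshold_step)) + 1
    thresholds = np.round(np.arange(n_thr) * threshold_step, 10)
    # preds[i, j, :] = combined score of triple i against threshold j
    preds = combined[:, None, :] > thresholds[None, :, None]
    wafs = _waf_binary(y, preds)
    flat = int(np.argmax(wafs))  # first maximizer = lexicographic-first
    i, j = divmod(flat, n_thr)
    return GridSolution(
        weights=tuple(float(v) for v in triples[i]),
        threshold=float(thresholds[j]),
        train_waf=float(wafs[i, j]),
    )


# ---------------------------------------------------------------------------
# decision-tree reference (thin adapter over the standard CART implementation)


def fit_decision_tree(train: FeatureTable | tuple, seed: int = 0) -> DecisionTreeClassifier:
    if isinstance(train, FeatureTable):
        X, y = train.X, train.y
    else:
        X, y = train
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("labels contain a single class")
    clf = DecisionTreeClassifier(random_state=seed)
    return clf.fit(np.asarray(X, dtype=float), y)


def predict_decision_tree(handle: DecisionTreeClassifier, features) -> np.ndarray:
    X = features.X if isinstance(features, FeatureTable) else np.asarray(features, float)
    return handle.predict(X).astype(int)


# ---------------------------------------------------------------------------
# sklearn estimators


class StaticCombinationClassifier(BaseEstimator, ClassifierMixin):
    """Single-aspect / Avg / Max score with a trained threshold.

    Fitting scans the threshold grid on the training set and keeps the
    smallest WAF-maximizing threshold (``threshold_``) together with the
    training WAF (``train_waf_``).
    """

    def __init__(self, kind: str = "Max", step: float = 0.01,
                 aspects: tuple[str, ...] = ("BP", "CC", "MF")):
        self.kind = kind
        self.step = step
        self.aspects = aspects

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        scores = combine_static(X, self.kind, tuple(self.aspects))
        self.threshold_, self.train_waf_ = fit_threshold(scores, y, self.step)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_")
        return combine_static(np.asarray(X, dtype=float), self.kind, tuple(self.aspects))

    def predict(self, X):
        return (self.decision_function(X) > self.threshold_).astype(int)


class GridCombinationClassifier(BaseEstimator, ClassifierMixin):
    """Weighted-average combiner fitted by exhaustive grid search."""

    def __init__(self, weight_step: float = 0.1, threshold_step: float = 0.05):
        self.weight_step = weight_step
        self.threshold_step = threshold_step

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise DegenerateTrainingError("labels contain a single class")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        sol = grid_search((X, y), self.weight_step, self.threshold_step)
        self.weights_ = sol.weights
        self.threshold_ = sol.threshold
        self.train_waf_ = sol.train_waf
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        w = np.asarray(self.weights_, dtype=float)
        return (np.asarray(X, dtype=float) @ w) / w.sum()

    def predict(self, X):
        return (self.decision_function(X) > self.threshold_).astype(int)
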