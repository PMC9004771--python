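"""Flat and hierarchical SVM staging with stratified cross-validated metrics.

The four diagnostic stages (NC, EMCI, LMCI, AD) are predicted either by a
single multiclass SVM (flat scheme, one-vs-one voting) or by a binary
decision tree of SVMs (hierarchical scheme): first AD vs everyone else,
then NC vs the two MCI stages, then EMCI vs LMCI. Ordering the splits by
how separable the super-classes are limits error propagation down the
tree and sidesteps some class-imbalance issues of the flat machine.

Every binary or flat model is a pipeline of per-feature z-scoring, t-test
edge selection and a linear SVM (C = 1 by default); in cross-validation
all three steps are refit inside each training fold, so the test fold
never influences scaling or selection.

Metrics follow the usual screening definitions: accuracy, sensitivity
TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN),
computed in exact rational arithmetic before conversion to float. On a
4x4 confusion matrix (rows = predicted, columns = ground truth) each is
macro-averaged over one-vs-rest reductions, and overall accuracy is
trace/total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import TTestSelector

CLASS_ORDER = ("NC", "EMCI", "LMCI", "AD")


@dataclass(frozen=True)
class HierarchySpec:
    """Ordered binary splits; each layer = (positive set, negative set, name)."""

    layers: tuple

    def __post_init__(self):
        for pos, neg, _ in self.layers:
            if set(pos) & set(neg):
                raise ValueError("layer positive and negative sets overlap")

    def __iter__(self):
        return iter(self.layers)


#: AD vs rest, then NC vs MCI, then EMCI vs LMCI.
DEFAULT_HIERARCHY = HierarchySpec(
    layers=(
        (frozenset({"AD"}), frozenset({"NC", "EMCI", "LMCI"}), "AD|rest"),
        (frozenset({"NC"}), frozenset({"EMCI", "LMCI"}), "NC|MCI"),
        (frozenset({"EMCI"}), frozenset({"LMCI"}), "EMCI|LMCI"),
    )
)


@dataclass
class ConfusionMatrix4:
    """Predicted x ground-truth counts over a fixed class order."""

    counts: np.ndarray
    classes: tuple = CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected {n}x{n} counts, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column_sums(self) -> np.ndarray:
        """Per-class ground-truth counts."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="predicted"),
            columns=pd.Index(self.classes, name="ground_truth"),
        )

    @classmethod
    def from_predictions(cls, y_pred, y_true, classes=CLASS_ORDER):
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for p, t in zip(y_pred, y_true):
            counts[idx[p], idx[t]] += 1
        return cls(counts, classes=tuple(classes))


@dataclass
class Metrics:
    """One set of screening metrics; NaN entries carry an 'undefined' flag."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: frozenset = frozenset()
    per_class: dict = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class MetricsReport:
    """Per-fold metrics with mean and standard deviation per metric."""

    per_fold: list = field(default_factory=list)  # of Metrics
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def from_folds(cls, per_fold) -> "MetricsReport":
        names = ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        mean, sd = {}, {}
        for name in names:
            vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
            valid = vals[np.isfinite(vals)]
            mean[name] = float(valid.mean()) if valid.size else math.nan
            sd[name] = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
        return cls(per_fold=list(per_fold), mean=mean, sd=sd)


def _ratio(num: int, den: int, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return float(Fraction(num, den))


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    """Exact metrics from binary counts; zero denominators yield NaN + flag."""
    undefined: set = set()
    return Metrics(
        accuracy=_ratio(tp + tn, tp + fp + fn + tn, "accuracy", undefined),
        sensitivity=_ratio(tp, tp + fn, "sensitivity", undefined),
        specificity=_ratio(tn, tn + fp, "specificity", undefined),
        ppv=_ratio(tp, tp + fp, "ppv", undefined),
        npv=_ratio(tn, tn + fn, "npv", undefined),
        undefined=frozenset(undefined),
    )


def compute_metrics(cm, positive_class=None) -> Metrics:
    """Metrics from a ConfusionMatrix4, a square count array, or 2x2 counts.

    For a multiclass matrix with ``positive_class`` given, the matrix is
    reduced one-vs-rest for that class. Without it, each metric is the
    macro average over all one-vs-rest reductions, and accuracy is the
    overall trace/total.
    """
    if isinstance(cm, ConfusionMatrix4):
        counts, classes = cm.counts, cm.classes
    else:
        counts = np.asarray(cm, dtype=int)
        if counts.shape == (2, 2):
            # rows = predicted (pos first), cols = truth (pos first)
            tp, fn = counts[0, 0], counts[1, 0]
            fp, tn = counts[0, 1], counts[1, 1]
            return binary_metrics(tp, fp, fn, tn)
        classes = tuple(range(counts.shape[0]))

    total = int(counts.sum())

    def ovr(ci: int) -> Metrics:
        tp = int(counts[ci, ci])
        fp = int(counts[ci, :].sum() - tp)
        fn = int(counts[:, ci].sum() - tp)
        tn = total - tp - fp - fn
        return binary_metrics(tp, fp, fn, tn)

    if positive_class is not None:
        return ovr(list(classes).index(positive_class))

    per_class = {c: ovr(i) for i, c in enumerate(classes)}
    undefined: set = set()
    macro = {}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        vals = [getattr(m, name) for m in per_class.values()]
        finite = [v for v in vals if not math.isnan(v)]
        if len(finite) < len(vals):
            undefined.add(name)
        macro[name] = sum(finite) / len(finite) if finite else math.nan
    accuracy = _ratio(int(np.trace(counts)), total, "accuracy", undefined)
    return Metrics(
        accuracy=accuracy,
        sensitivity=macro["sensitivity"],
        specificity=macro["specificity"],
        ppv=macro["ppv"],
        npv=macro["npv"],
        undefined=frozenset(undefined),
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def make_binary_pipeline(alpha: float = 0.05, C: float = 1.0, kernel: str = "linear") -> Pipeline:
    """z-score -> t-test selection -> SVM, the unit classifier everywhere."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("select", TTestSelector(alpha=alpha)),
            ("svm", SVC(kernel=kernel, C=C)),
        ]
    )


def make_flat_pipeline(alpha: float = 0.05, C: float = 1.0, kernel: str = "linear") -> Pipeline:
    """Flat 4-class machine; SVC uses one-vs-one voting internally."""
    return make_binary_pipeline(alpha=alpha, C=C, kernel=kernel)


def train_binary(train_features, train_labels, mask=None, alpha=0.05, C=1.0, kernel="linear"):
    """Fit one binary SVM pipeline; errors if only one class is present.

    ``mask`` (a ConnectionMask or boolean array over features) restricts
    the candidate edges before the in-pipeline selection.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if mask is not None:
        flat = mask.values[~np.eye(mask.values.shape[0], dtype=bool)] if hasattr(mask, "values") else np.asarray(mask)
        X = X[:, np.asarray(flat, dtype=bool)]
    return make_binary_pipeline(alpha=alpha, C=C, kernel=kernel).fit(X, y)


class HierarchicalSVC(ClassifierMixin, BaseEstimator):
    """Binary-tree multiclass SVM following a :class:`HierarchySpec`.

    Each layer trains an independent pipeline on the subjects whose true
    label belongs to that layer's positive or negative set; prediction
    walks the layers, stopping at the first positive decision.
    """

    def __init__(self, hierarchy: HierarchySpec = DEFAULT_HIERARCHY,
                 alpha: float = 0.05, C: float = 1.0, kernel: str = "linear"):
        self.hierarchy = hierarchy
        self.alpha = alpha
        self.C = C
        self.kernel = kernel

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.unique(y)
        self.models_ = []
        for pos, neg, name in self.hierarchy:
            in_layer = np.isin(y, list(pos | neg))
            yy = np.where(np.isin(y[in_layer], list(pos)), 1, 0)
            if np.unique(yy).size < 2:
                raise ValueError(f"layer {name!r} training set has a single class")
            model = make_binary_pipeline(self.alpha, self.C, self.kernel)
            model.fit(X[in_layer], yy)
            self.models_.append((model, pos, neg, name))
        return self

    def predict(self, X):
        if not hasattr(self, "models_"):
            raise ValueError("HierarchicalSVC is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=object)
        undecided = np.ones(X.shape[0], dtype=bool)
        for li, (model, pos, neg, _) in enumerate(self.models_):
            if not undecided.any():
                break
            pred = model.predict(X[undecided]) == 1
            idx = np.flatnonzero(undecided)
            last = li == len(self.models_) - 1
            pos_label = _single_label(pos)
            for local, decided_pos in enumerate(pred):
                gi = idx[local]
                if decided_pos:
                    out[gi] = pos_label
                    undecided[gi] = False
                elif last:
                    out[gi] = _single_label(neg)
                    undecided[gi] = False
        return out


def _single_label(classes) -> str:
    if len(classes) != 1:
        raise ValueError(
            f"cannot emit a final label from the multi-class set {sorted(classes)}"
        )
    return next(iter(classes))


def predict_hierarchical(models, x, spec: HierarchySpec = DEFAULT_HIERARCHY):
    """Route one feature vector through per-layer binary models.

    ``models`` is one object per layer exposing ``predict``; a positive
    decision at a layer emits that layer's positive class, a negative
    decision at the final layer emits the final negative class.
    """
    layers = list(spec)
    if len(models) != len(layers):
        raise ValueError(f"need {len(layers)} layer models, got {len(models)}")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    for li, (model, (pos, neg, _)) in enumerate(zip(models, layers)):
        if model is None:
            raise ValueError(f"missing model for layer {li}")
        if np.asarray(model.predict(x)).ravel()[0] == 1:
            return _single_label(pos)
        if li == len(layers) - 1:
            return _single_label(neg)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _build_estimator(scheme, alpha, C, kernel):
    if scheme == "flat":
        return make_flat_pipeline(alpha=alpha, C=C, kernel=kernel)
    if scheme == "hierarchical":
        scheme = DEFAULT_HIERARCHY
    if isinstance(scheme, HierarchySpec):
        return HierarchicalSVC(hierarchy=scheme, alpha=alpha, C=C, kernel=kernel)
    raise ValueError(f"unknown scheme {scheme!r}")


def crossvalidate(X, y, scheme="hierarchical", k: int = 10, seed: int = 42,
                  alpha: float = 0.05, C: float = 1.0, kernel: str = "linear",
                  classes=CLASS_ORDER):
    """Stratified k-fold CV; selection and scaling are refit per fold.

    Returns (pooled ConfusionMatrix4, MetricsReport). The pooled matrix
    accumulates every test-fold prediction; the report carries per-fold
    macro metrics with mean and SD.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    present = [c for c in classes if c in set(y)]
    counts = {c: int((y == c).sum()) for c in present}
    too_small = [c for c, n in counts.items() if n < k]
    if too_small:
        raise ValueError(
            f"classes {too_small} have fewer than k={k} subjects; use a smaller k"
        )
    base = _build_estimator(scheme, alpha, C, kernel)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    per_fold = []
    idx = {c: i for i, c in enumerate(classes)}
    for train_idx, test_idx in skf.split(X, y.astype(str)):
        model = clone(base)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        fold_counts = np.zeros_like(pooled)
        for p, t in zip(pred, y[test_idx]):
            fold_counts[idx[p], idx[t]] += 1
        pooled += fold_counts
        per_fold.append(compute_metrics(ConfusionMatrix4(fold_counts, classes=tuple(classes))))
    return ConfusionMatrix4(pooled, classes=tuple(classes)), MetricsReport.from_folds(per_fold)


def pairwise_binary_accuracies(X, y, k: int = 10, seed: int = 42,
                               alpha: float = 0.05, C: float = 1.0,
                               kernel: str = "linear") -> pd.DataFrame:
    """CV accuracy (mean +/- SD) for every class pair; used to motivate the
    hierarchy ordering (most separable super-classes split first)."""
    y = np.asarray(y, dtype=object)
    classes = [c for c in CLASS_ORDER if c in set(y)]
    rows = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            sel = np.isin(y, [a, b])
            cm, report = crossvalidate(
                np.asarray(X, dtype=float)[sel], y[sel], scheme="flat",
                k=k, seed=seed, alpha=alpha, C=C, kernel=kernel, classes=(a, b),
            )
            rows.append((f"{a} vs {b}", report.mean["accuracy"], report.sd["accuracy"]))
    return pd.DataFrame(rows, columns=["pair", "accuracy_mean", "accuracy_sd"])
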