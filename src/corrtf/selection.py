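"""Edge selection by two-sample t-tests between diagnostic groups.

Each directed CorrTF edge is tested independently with a two-sided Welch
t-test; edges with p below alpha (default 0.05) feed the classifier, and
the smallest p-values define the most discriminative connections. No
multiple-testing correction is applied by default, matching common
practice of reporting raw edge-level p-values; an optional
Benjamini-Hochberg FDR flag is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

logger = logging.getLogger(__name__)


@dataclass
class PValueMatrix:
    """Directed per-edge p-values between two groups, shape R x R.

    The diagonal is NaN (self-edges are never tested); ``degenerate`` flags
    edges where both groups had zero variance and equal means.
    """

    values: np.ndarray
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    roi_ids: list = None
    degenerate: np.ndarray = None

    def __post_init__(self):
        if self.roi_ids is None:
            self.roi_ids = list(range(1, self.values.shape[0] + 1))
        off = ~np.eye(self.values.shape[0], dtype=bool)
        vals = self.values[off]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("off-diagonal p-values must lie in [0, 1]")


@dataclass
class ConnectionMask:
    """Boolean off-diagonal mask of selected edges at threshold alpha."""

    values: np.ndarray
    alpha: float

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.values))


def welch_pvalues(a: np.ndarray, b: np.ndarray):
    """Columnwise two-sided Welch t-test p-values with degenerate handling.

    Columns where both groups are constant and identical get p = 1 and a
    degenerate flag (no evidence either way); constant-but-different
    columns come out p ~ 0 from the test itself.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    return p, degenerate


def _stack_features(features) -> np.ndarray:
    """Accept FeatureVector lists or a 2-D array; return (n_subjects, n_edges)."""
    if hasattr(features, "ndim"):
        return np.asarray(features, dtype=float)
    rows, index0 = [], None
    for fv in features:
        if index0 is None:
            index0 = fv.edge_index
        elif fv.edge_index != index0:
            raise ValueError("subjects have inconsistent edge indexing")
        rows.append(fv.values)
    return np.vstack(rows)


def _edges_to_matrix(flat: np.ndarray, n_rois: int, fill=np.nan) -> np.ndarray:
    out = np.full((n_rois, n_rois), fill, dtype=float)
    out[~np.eye(n_rois, dtype=bool)] = flat
    return out


def ttest_connections(features_a, features_b, group_a="A", group_b="B") -> PValueMatrix:
    """Per-edge Welch t-test between two groups of CorrTF feature vectors."""
    A = _stack_features(features_a)
    B = _stack_features(features_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different numbers of edges")
    n_edges = A.shape[1]
    n_rois = int(round((1 + np.sqrt(1 + 4 * n_edges)) / 2))
    if n_rois * (n_rois - 1) != n_edges:
        raise ValueError(f"{n_edges} features is not R*(R-1) for integer R")
    p, degenerate = welch_pvalues(A, B)
    roi_ids = None
    if not hasattr(features_a, "ndim"):
        first = next(iter(features_a))
        roi_ids = sorted({e[0] for e in first.edge_index} | {e[1] for e in first.edge_index})
    pmat = _edges_to_matrix(p, n_rois)
    dmat = _edges_to_matrix(degenerate.astype(float), n_rois, fill=0.0).astype(bool)
    return PValueMatrix(
        pmat, group_a=group_a, group_b=group_b,
        n_a=A.shape[0], n_b=B.shape[0], roi_ids=roi_ids, degenerate=dmat,
    )


def select_features(pvals: PValueMatrix, alpha: float = 0.05, fdr: bool = False) -> ConnectionMask:
    """Strictly-below-alpha mask over off-diagonal edges.

    With ``fdr=True`` the Benjamini-Hochberg procedure is applied to the
    off-diagonal p-values first.
    """
    R = pvals.values.shape[0]
    off = ~np.eye(R, dtype=bool)
    p = pvals.values.copy()
    if fdr:
        flat = p[off]
        order = np.argsort(flat)
        m = flat.size
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, flat[order[rank]] * m / (rank + 1))
            adj[order[rank]] = running
        p[off] = adj
    mask = np.zeros((R, R), dtype=bool)
    mask[off] = p[off] < alpha
    selected = ConnectionMask(mask, alpha=alpha)
    logger.info(
        "selected %d/%d edges at alpha=%g (%s vs %s)",
        selected.n_selected, int(off.sum()), alpha, pvals.group_a, pvals.group_b,
    )
    return selected


def rank_discriminative(pvals: PValueMatrix, k: int = 20) -> pd.DataFrame:
    """Top-k edges ascending by p; ties broken by row-major edge position.

    Returns a DataFrame with columns (roi_a, roi_b, p_value).
    """
    R = pvals.values.shape[0]
    rows = []
    for i in range(R):
        for j in range(R):
            if i != j:
                rows.append((pvals.roi_ids[i], pvals.roi_ids[j], pvals.values[i, j]))
    df = pd.DataFrame(rows, columns=["roi_a", "roi_b", "p_value"])
    if k > len(df):
        warnings.warn(f"k={k} exceeds the {len(df)} available edges; returning all")
        k = len(df)
    # mergesort is stable, preserving row-major order among ties
    return df.sort_values("p_value", kind="mergesort").head(k).reset_index(drop=True)


class TTestSelector(SelectorMixin, BaseEstimator):
    """Per-feature t-test selection usable inside sklearn pipelines.

    For binary targets, a Welch two-sample test per feature; for more than
    two classes, the union of all pairwise tests (a feature is kept if it
    separates any class pair at alpha). If nothing survives, all features
    are retained with a warning so downstream fitting never sees an empty
    design matrix.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least two classes to select features")
        support = np.zeros(X.shape[1], dtype=bool)
        pmin = np.ones(X.shape[1])
        for a_idx in range(classes.size):
            for b_idx in range(a_idx + 1, classes.size):
                p, _ = welch_pvalues(X[y == classes[a_idx]], X[y == classes[b_idx]])
                support |= p < self.alpha
                pmin = np.minimum(pmin, p)
        if not support.any():
            warnings.warn(
                "no feature passed the t-test threshold; falling back to all features"
            )
            support = np.ones(X.shape[1], dtype=bool)
        self.support_ = support
        self.pvalues_ = pmin
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


def write_pvalues_tsv(pvals: PValueMatrix, path, k=None) -> None:
    if k is None:
        R = pvals.values.shape[0]
        k = R * (R - 1)
    rank_discriminative(pvals, k=k).to_csv(path, sep="\t", index=False)
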