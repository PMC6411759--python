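"""Information-gain ranking of feature columns.

IG of a feature V for binary labels U is the entropy drop
``IG = H(U) - H(U|V)`` in bits.  Continuous feature columns are discretized
into equal-width bins over their observed range before the conditional
entropy is computed; a constant column therefore has IG 0 and no column can
exceed the label entropy.

Ranking is reporting/interpretation machinery: the fused classifier trains
on full feature vectors by default, and top-N selection is exposed for
experimentation via :class:`InformationGainSelector`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_BINS = 10


def entropy(labels: Sequence) -> float:
    """Shannon entropy of a class sequence, in bits; 0 for a single class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label sequence is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretize(column: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning over the observed range; constants map to one bin."""
    lo, hi = column.min(), column.max()
    if lo == hi:
        return np.zeros(column.shape, dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    # rightmost edge inclusive
    return np.clip(np.digitize(column, edges[1:-1], right=False), 0, bins - 1)


def information_gain(feature: Sequence, labels: Sequence, bins: int = DEFAULT_BINS) -> float:
    """IG (bits) of one feature column for the labels.

    ``bins`` controls the equal-width discretization of continuous values
    (ignored for columns that are already few-valued beyond bin resolution
    in effect, since binning a discrete column is harmless).
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if feature.shape[0] != labels.shape[0]:
        raise ValueError(
            f"feature has {feature.shape[0]} rows but labels {labels.shape[0]}"
        )
    if bins < 2:
        raise ValueError("bins must be >= 2")
    h_u = entropy(labels)
    if h_u == 0.0:
        return 0.0
    v = _discretize(feature, bins)
    h_cond = 0.0
    n = len(labels)
    for val in np.unique(v):
        mask = v == val
        h_cond += (mask.sum() / n) * entropy(labels[mask])
    return max(0.0, h_u - h_cond)


@dataclass
class IGRanking:
    """Ranked features: dense ranks (ties share a rank), scores non-increasing."""

    table: pd.DataFrame  # columns: rank, feature, ig, mean_pos, mean_neg

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def __len__(self) -> int:
        return len(self.table)


def rank_features(
    matrix,
    labels: Sequence,
    top_n: int = 20,
    bins: int = DEFAULT_BINS,
    feature_names: Sequence[str] | None = None,
) -> IGRanking:
    """Score every column by IG and return the top ``top_n``.

    ``matrix`` may be a DataFrame (column names used) or an array with
    ``feature_names``.  The report includes per-class mean feature values.
    Ties share a dense rank and keep stable (input-order) name order.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if feature_names is None:
            raise ValueError("feature_names required for array input")
        names = list(feature_names)
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length does not match matrix width")
    y = np.asarray(labels)
    if top_n > X.shape[1]:
        warnings.warn(
            f"top_n={top_n} exceeds the {X.shape[1]} available features; returning all",
            stacklevel=2,
        )
        top_n = X.shape[1]
    ig = np.array([information_gain(X[:, j], y, bins=bins) for j in range(X.shape[1])])
    order = np.argsort(-ig, kind="stable")[:top_n]
    scores = np.round(ig[order], 12)
    # dense ranking: equal scores share a rank
    ranks = np.ones(len(order), dtype=int)
    for i in range(1, len(order)):
        ranks[i] = ranks[i - 1] + (0 if scores[i] == scores[i - 1] else 1)
    pos, neg = y == np.max(y), y == np.min(y)
    table = pd.DataFrame(
        {
            "rank": ranks,
            "feature": [names[j] for j in order],
            "ig": ig[order],
            "mean_pos": [X[pos, j].mean() for j in order],
            "mean_neg": [X[neg, j].mean() for j in order],
        }
    )
    return IGRanking(table=table)


class InformationGainSelector(TransformerMixin, BaseEstimator):
    """Keep the ``top_n`` columns by information gain (experimentation aid)."""

    def __init__(self, top_n: int = 20, bins: int = DEFAULT_BINS):
        self.top_n = top_n
        self.bins = bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.scores_ = np.array(
            [information_gain(X[:, j], y, bins=self.bins) for j in range(X.shape[1])]
        )
        keep = min(self.top_n, X.shape[1])
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[np.argsort(-self.scores_, kind="stable")[:keep]] = True
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]
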