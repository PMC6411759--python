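"""Performance metrics, cross-validation protocol and positional enrichment tests.

Threshold-dependent metrics are the standard confusion-table quantities:

    Sn  = TP / (TP + FN)            (sensitivity / recall on positives)
    Sp  = TN / (TN + FP)            (specificity)
    Ac  = (TP + TN) / total         (accuracy)
    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TP+FP)(TN+FP)(TP+FN))

A metric with a zero denominator is reported as missing (None), never
coerced to 0.  AUC uses the rank (Mann-Whitney) formulation with ties
counted 1/2, which equals the trapezoidal ROC area for tie-free scores and
stays well-defined with ties.

Positional enrichment compares two peptide groups over the 15 N-terminal
positions ('O'-filled analysis windows): per-position, per-residue Welch
t-tests on presence indicators (the two-sample-logo computation), and
per-position Kruskal-Wallis tests on real-valued positional profiles
(e.g. conservation or physicochemical channels) with Bonferroni correction
across positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_io import AMINO_ACIDS, ANALYSIS_FILL, ANALYSIS_SPAN

#: Alphabet of the positional analysis window: 20 residues plus the 'O' fill.
ANALYSIS_ALPHABET = AMINO_ACIDS + ANALYSIS_FILL


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Confusion-table metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Sn/Sp/Ac/MCC (None where undefined) plus optional AUC and level tag."""

    Sn: float | None
    Sp: float | None
    Ac: float | None
    MCC: float | None
    AUC: float | None = None
    level: str | None = None

    def to_dict(self) -> dict:
        return {
            "level": self.level, "Sn": self.Sn, "Sp": self.Sp,
            "Ac": self.Ac, "MCC": self.MCC, "AUC": self.AUC,
        }


def confusion_from_scores(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> ConfusionCounts:
    """Confusion counts under the rule: positive iff score >= cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= cutoff
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def compute_metrics(counts: ConfusionCounts, level: str | None = None) -> MetricsReport:
    """Sn, Sp, Ac and MCC from a confusion table; undefined -> None."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (tn + fp) if (tn + fp) > 0 else None
    ac = (tp + tn) / counts.total if counts.total > 0 else None
    marginals = (tn + fn) * (tp + fp) * (tn + fp) * (tp + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(marginals) if marginals > 0 else None
    return MetricsReport(Sn=sn, Sp=sp, Ac=ac, MCC=mcc, level=level)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count 1/2); labels must contain both classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes")
    r = stats.rankdata(scores)
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, pd.DataFrame]:
    """AUC plus the ROC point list (1-Sp, Sn) over all score cutoffs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc = rank_auc(s, y)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # one ROC vertex per distinct score, plus the (0, 0) origin
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    n_pos, n_neg = tps[-1], fps[-1]
    points = pd.DataFrame(
        {
            "cutoff": np.r_[np.inf, s_sorted[last_of_block]],
            "fpr": np.r_[0.0, fps[last_of_block] / n_neg],
            "tpr": np.r_[0.0, tps[last_of_block] / n_pos],
        }
    )
    return auc, points


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Out-of-fold scores and per-fold / averaged metrics from k-fold CV."""

    oof_scores: pd.DataFrame      # one column per encoder + 'combined'
    fold_id: np.ndarray
    weights: "object"             # ensemble.EnsembleWeights
    thresholds: "object"          # ensemble.ThresholdSet
    per_fold: pd.DataFrame        # fold, level, Sn, Sp, Ac, MCC, AUC
    averaged: pd.DataFrame        # level, Sn, Sp, Ac, MCC, AUC (fold means)


def kfold_cv(
    features: dict,
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
    n_trees: int = 1000,
    weight_step: float = 0.05,
    sp_targets: Sequence[float] = (0.9, 0.8, 0.7),
) -> CVReport:
    """Stratified k-fold CV of the full per-encoder + fused pipeline.

    Folds are random, stratified and near-equal; every sample is scored
    exactly once by a model that did not train on it.  The out-of-fold
    encoder scores feed the weight grid search and the specificity-anchored
    threshold calibration; per-fold metrics are evaluated at the calibrated
    cutoffs and averaged over folds (a missing metric in a fold is skipped
    in the mean).
    """
    from . import ensemble  # local import: ensemble also uses rank_auc

    y = np.asarray(labels, dtype=int)
    clf = ensemble.AIPEnsembleClassifier(
        cv=k, n_trees=n_trees, weight_step=weight_step,
        sp_targets=tuple(sp_targets), random_state=seed,
    )
    clf.fit(features, y, refit=False)
    oof = clf.cv_scores_.copy()
    fold_id = clf.cv_fold_
    level_names = clf.thresholds_.levels
    rows = []
    for fold in np.unique(fold_id):
        mask = fold_id == fold
        s, yy = oof["combined"].to_numpy()[mask], y[mask]
        try:
            auc = rank_auc(s, yy)
        except EvaluationError:
            auc = None
        for level in level_names:
            rep = compute_metrics(
                confusion_from_scores(s, yy, clf.thresholds_.cutoff(level)),
                level=level,
            )
            rows.append(
                {"fold": int(fold), "level": level, "Sn": rep.Sn, "Sp": rep.Sp,
                 "Ac": rep.Ac, "MCC": rep.MCC, "AUC": auc}
            )
    per_fold = pd.DataFrame(rows)
    averaged = (
        per_fold.drop(columns="fold").groupby("level", sort=False).mean()
        .reset_index()
    )
    return CVReport(
        oof_scores=oof, fold_id=fold_id, weights=clf.weights_,
        thresholds=clf.thresholds_, per_fold=per_fold, averaged=averaged,
    )


# ---------------------------------------------------------------------------
# Positional enrichment statistics
# ---------------------------------------------------------------------------

def _indicator_cube(windows: Sequence[str], span: int) -> np.ndarray:
    """(n, span, |alphabet|) 0/1 cube of residue presence."""
    lut = {ch: i for i, ch in enumerate(ANALYSIS_ALPHABET)}
    cube = np.zeros((len(windows), span, len(ANALYSIS_ALPHABET)))
    for i, w in enumerate(windows):
        if len(w) != span:
            raise EvaluationError(
                f"analysis window {w!r} has length {len(w)}, expected {span}"
            )
        for j, ch in enumerate(w):
            try:
                cube[i, j, lut[ch]] = 1.0
            except KeyError:
                raise EvaluationError(f"symbol {ch!r} outside the analysis alphabet")
    return cube


def positional_welch(
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    span: int = ANALYSIS_SPAN,
) -> pd.DataFrame:
    """Per-position, per-residue Welch t-tests between two peptide groups.

    Inputs are 'O'-filled analysis windows.  For each position and residue
    the per-peptide presence indicator is compared between groups with
    Welch's unequal-variance t-test; ``direction`` is 'over' when the
    residue is more frequent in ``group_a``.  Rows with p < alpha are
    flagged.  Identical groups (or zero-variance cells) yield no flags.
    """
    if not len(group_a) or not len(group_b):
        raise EvaluationError("both groups must be non-empty")
    A = _indicator_cube(group_a, span)
    B = _indicator_cube(group_b, span)
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # zero-variance cells (residue absent or constant) yield NaN p-values,
        # which are handled below; silence the precision-loss chatter
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(A, B, axis=0, equal_var=False)
        p = np.asarray(res.pvalue)
    freq_a, freq_b = A.mean(axis=0), B.mean(axis=0)
    rows = []
    for j in range(span):
        for r, residue in enumerate(ANALYSIS_ALPHABET):
            pj = p[j, r]
            rows.append(
                {
                    "position": j + 1,
                    "residue": residue,
                    "freq_a": freq_a[j, r],
                    "freq_b": freq_b[j, r],
                    "direction": "over" if freq_a[j, r] >= freq_b[j, r] else "under",
                    "p": pj if np.isfinite(pj) else np.nan,
                    "flagged": bool(np.isfinite(pj) and pj < alpha),
                }
            )
    return pd.DataFrame(rows)


def positional_kw(
    profile_a,
    profile_b,
    n_positions: int = ANALYSIS_SPAN,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position Kruskal-Wallis tests with Bonferroni correction.

    ``profile_a``/``profile_b`` are (n_peptides, n_positions) arrays of real
    per-position values (NaN marks positions beyond a peptide's length and is
    dropped).  Corrected p = min(1, p * n_positions); positions with
    corrected p < alpha are flagged.  A position where all values tie gets
    p = 1.
    """
    A = np.asarray(profile_a, dtype=float)
    B = np.asarray(profile_b, dtype=float)
    if A.shape[1] != n_positions or B.shape[1] != n_positions:
        raise EvaluationError(
            f"profiles must have {n_positions} aligned positions "
            f"(got {A.shape[1]} and {B.shape[1]})"
        )
    rows = []
    for j in range(n_positions):
        a = A[:, j][np.isfinite(A[:, j])]
        b = B[:, j][np.isfinite(B[:, j])]
        if a.size == 0 or b.size == 0:
            stat, p = np.nan, 1.0
        else:
            try:
                with np.errstate(invalid="ignore"):
                    stat, p = stats.kruskal(a, b)
                if not np.isfinite(p):  # all values tied
                    stat, p = 0.0, 1.0
            except ValueError:  # all values identical (older scipy raises)
                stat, p = 0.0, 1.0
        p_corr = min(1.0, p * n_positions)
        rows.append(
            {"position": j + 1, "statistic": stat, "p": p,
             "p_bonferroni": p_corr, "flagged": bool(p_corr < alpha)}
        )
    return pd.DataFrame(rows)


# Helpers producing positional profile matrices for the KW contrast --------

def pssm_position_profile(
    profiles: Sequence, residue: str | None = None, span: int = ANALYSIS_SPAN
) -> np.ndarray:
    """Per-peptide, per-position conservation channel from PSSM profiles.

    By default the average squashed PSSM value of the position (mean over the
    20 residue columns); with ``residue`` given, that residue's squashed
    column, which contrasts classes that differ in residue usage.  Positions
    beyond a profile's length are NaN.
    """
    from .encoders import AA_INDEX

    out = np.full((len(profiles), span), np.nan)
    col = AA_INDEX[residue] if residue is not None else None
    for i, prof in enumerate(profiles):
        m = prof.squashed() if not getattr(prof, "_presquashed", False) else prof.matrix
        upto = min(span, m.shape[0])
        out[i, :upto] = m[:upto, col] if col is not None else m[:upto].mean(axis=1)
    return out


def aaindex_position_profile(
    records: Sequence, table, index_id: str, span: int = ANALYSIS_SPAN
) -> np.ndarray:
    """Per-peptide, per-position values of one physicochemical index."""
    row = table.values.loc[index_id]
    out = np.full((len(records), span), np.nan)
    for i, rec in enumerate(records):
        for j, ch in enumerate(rec.sequence[:span]):
            out[i, j] = row[ch]
    return out
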