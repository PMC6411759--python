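"""Per-encoder random forests, weighted score fusion and threshold calibration.

Each active feature encoding gets its own random forest whose score for a
peptide is the fraction of trees voting positive (the forest's probability
estimate).  The five encoder scores are fused linearly,

    combined = w1*SPIDER2 + w2*PEP2D + w3*KSAAP + w4*AAindex + w5*pKSAAP,

with non-negative weights summing to 1.  The weight vector is found by
exhaustive search over the 0.05-step simplex lattice, maximizing the AUC of
the combined score on *out-of-fold* cross-validation scores (resubstitution
scores are never used, so the fused AUC is not optimistically biased).
Decision cutoffs for high/moderate/low confidence calls are then anchored to
target specificities (0.9/0.8/0.7 by default) on the same out-of-fold
combined scores.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluation import rank_auc

log = logging.getLogger(__name__)

#: Frozen encoder order of the fusion formula (w1..w5).
ENCODER_ORDER = ("SPIDER2", "PEP2D", "KSAAP", "AAindex", "pKSAAP")
#: Default active encoders: the final fused model carries zero weight on the
#: structural encoders, which activate only when structural tables are given.
DEFAULT_ENCODERS = ("KSAAP", "AAindex", "pKSAAP")
DEFAULT_SP_TARGETS = (0.9, 0.8, 0.7)
LEVEL_NAMES = ("high", "moderate", "low")


class EnsembleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Forest scoring
# ---------------------------------------------------------------------------

@dataclass
class ForestConfig:
    """Random-forest settings: 1000 gini trees with sqrt-of-K feature
    subsampling per split by default."""

    n_trees: int = 1000
    criterion: str = "gini"
    max_features: str | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise EnsembleError("n_trees must be >= 1")


def train_forest(features: np.ndarray, labels: Sequence[int],
                 config: ForestConfig | None = None) -> RandomForestClassifier:
    """Fit one random forest on a feature matrix.

    Scores from the returned model (``predict_proba[:, 1]``) are the
    fraction of trees voting positive, in [0, 1]; a fixed seed makes the
    scores reproducible.
    """
    config = config or ForestConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.isfinite(X).all():
        raise EnsembleError("feature matrix contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EnsembleError("training labels contain a single class")
    if counts.min() < 2:
        raise EnsembleError("need at least 2 samples per class")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.criterion,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def forest_scores(model: RandomForestClassifier, features: np.ndarray) -> np.ndarray:
    """Positive-class probability (fraction of trees voting positive)."""
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return model.predict_proba(np.asarray(features, dtype=float))[:, pos_col]


# ---------------------------------------------------------------------------
# Weight fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleWeights:
    """Five fusion weights ordered (SPIDER2, PEP2D, KSAAP, AAindex, pKSAAP)."""

    values: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (5,):
            raise EnsembleError("exactly five weights required")
        if (v < 0).any() or (v > 1).any():
            raise EnsembleError("weights must lie in [0, 1]")
        if abs(v.sum() - 1.0) > 1e-9:
            raise EnsembleError(f"weights must sum to 1 (got {v.sum()!r})")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ENCODER_ORDER, self.values))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "EnsembleWeights":
        return cls(tuple(float(mapping.get(name, 0.0)) for name in ENCODER_ORDER))


def combine_scores(scores: Sequence[float], weights: EnsembleWeights) -> float:
    """Weighted sum of the five encoder scores (Σ w_i * score_i).

    Encoders with weight 0 contribute nothing and may have a missing (NaN)
    score; any scored encoder must lie in [0, 1].
    """
    w = weights.as_array()
    s = np.asarray(scores, dtype=float)
    if s.shape != (5,):
        raise EnsembleError("expected five scores in ENCODER_ORDER")
    active = w > 0
    if np.isnan(s[active]).any():
        raise EnsembleError("missing score for an encoder with non-zero weight")
    valid = ~np.isnan(s)
    if ((s[valid] < 0) | (s[valid] > 1)).any():
        raise EnsembleError("encoder scores must lie in [0, 1]")
    return float(np.sum(w[active] * s[active]))


def weight_lattice(n_encoders: int, step: float = 0.05) -> np.ndarray:
    """All non-negative weight vectors on the ``step`` lattice summing to 1.

    Enumerated in lexicographic order over the integer compositions of
    ``1/step`` into ``n_encoders`` parts; this order is the documented
    tie-break order of the grid search.  For 5 encoders at step 0.05 the
    lattice has C(24, 4) = 10,626 vectors.
    """
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise EnsembleError("1/step must be an integer")
    rows = []
    for combo in itertools.product(range(units + 1), repeat=n_encoders - 1):
        rest = units - sum(combo)
        if rest >= 0:
            rows.append(combo + (rest,))
    return np.asarray(rows, dtype=float) * step


def grid_search_weights(
    cv_scores: np.ndarray,
    labels: Sequence[int],
    step: float = 0.05,
    encoder_names: Sequence[str] = ENCODER_ORDER,
) -> tuple[EnsembleWeights, float]:
    """Exhaustive simplex search for the AUC-maximizing fusion weights.

    ``cv_scores`` is an (n_samples, n_encoders) matrix of *out-of-fold*
    scores in ``encoder_names`` column order.  Ties are broken by the first
    vector encountered in the lexicographic lattice enumeration.  Returns
    the winning weights (embedded into the full five-encoder order, absent
    encoders at 0) and the pooled out-of-fold AUC they achieve.
    """
    S = np.asarray(cv_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if S.ndim != 2 or S.shape[0] != y.shape[0]:
        raise EnsembleError("cv_scores must be (n_samples, n_encoders) aligned with labels")
    if len(encoder_names) != S.shape[1]:
        raise EnsembleError("encoder_names must match cv_scores columns")
    unknown = set(encoder_names) - set(ENCODER_ORDER)
    if unknown:
        raise EnsembleError(f"unknown encoder(s) {sorted(unknown)}")
    if len(np.unique(y)) < 2:
        raise EnsembleError("grid search requires both classes")
    W = weight_lattice(S.shape[1], step=step)
    combined = S @ W.T                      # (n_samples, n_candidates)
    from scipy.stats import rankdata
    r = rankdata(combined, axis=0)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    aucs = (r[y == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    best = int(np.argmax(aucs))             # first maximizer in lattice order
    chosen = dict(zip(encoder_names, W[best]))
    return EnsembleWeights.from_dict(chosen), float(aucs[best])


# ---------------------------------------------------------------------------
# Specificity-anchored thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSet:
    """Score cutoffs per confidence level with the specificity each achieves.

    Higher levels demand higher specificity, so cutoffs are non-increasing
    from high to low and the achieved Sp is non-increasing the same way.
    """

    cutoffs: dict[str, float]
    achieved_sp: dict[str, float]
    targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = [self.cutoffs[lv] for lv in self.levels]
        if any(c[i] < c[i + 1] for i in range(len(c) - 1)):
            raise EnsembleError("cutoffs must be non-increasing from high to low")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.cutoffs.keys())

    def cutoff(self, level: str) -> float:
        return self.cutoffs[level]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "target_sp": [self.targets.get(lv) for lv in self.levels],
                "cutoff": [self.cutoffs[lv] for lv in self.levels],
                "achieved_sp": [self.achieved_sp[lv] for lv in self.levels],
            }
        )


def calibrate_thresholds(
    scores: Sequence[float],
    labels: Sequence[int],
    sp_targets: Sequence[float] = DEFAULT_SP_TARGETS,
    level_names: Sequence[str] = LEVEL_NAMES,
) -> ThresholdSet:
    """Choose decision cutoffs achieving target specificities.

    Prediction rule: positive iff score >= cutoff.  For each target the
    cutoff is the smallest candidate (the observed scores plus one value
    just above the maximum) whose achieved specificity — the fraction of
    negatives scored strictly below it — meets the target.  Targets must be
    given from most to least strict so that cutoffs order high >= moderate
    >= low.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise EnsembleError("calibration requires both classes")
    if list(sp_targets) != sorted(sp_targets, reverse=True):
        raise EnsembleError("sp_targets must be non-increasing (strictest first)")
    neg = np.sort(s[y == 0])
    top = s.max()
    eps = np.spacing(top) if np.isfinite(top) else 1e-12
    candidates = np.unique(np.r_[s, top + eps])
    # achieved Sp at cutoff c = fraction of negatives < c
    sp_at = np.searchsorted(neg, candidates, side="left") / neg.size
    cutoffs, achieved, targets = {}, {}, {}
    for name, target in zip(level_names, sp_targets):
        ok = np.nonzero(sp_at >= target)[0]
        if ok.size == 0:  # unreachable: Sp at max+eps is 1
            idx = len(candidates) - 1
        else:
            idx = int(ok[0])
        if candidates[idx] > top:
            warnings.warn(
                f"specificity target {target} only attainable with a cutoff above "
                "every observed score; no peptide will be called at this level",
                stacklevel=2,
            )
        cutoffs[name] = float(candidates[idx])
        achieved[name] = float(sp_at[idx])
        targets[name] = float(target)
    return ThresholdSet(cutoffs=cutoffs, achieved_sp=achieved, targets=targets)


# ---------------------------------------------------------------------------
# Fused classifier
# ---------------------------------------------------------------------------

class AIPEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Fused anti-inflammatory peptide classifier.

    ``X`` is a mapping from encoder name to an (n_peptides, dim) feature
    matrix (see :func:`aipkit.encoders.build_feature_matrices`); any subset
    of the five encoders may be supplied and absent ones carry weight 0.
    Fitting runs stratified ``cv``-fold cross-validation to collect
    out-of-fold scores per encoder, grid-searches the fusion weights on
    them, calibrates specificity-anchored cutoffs, then refits each
    encoder's forest on the full data.

    Fitted attributes: ``forests_`` (per-encoder models), ``weights_``,
    ``thresholds_``, ``cv_scores_`` (out-of-fold score table incl. the
    combined column), ``cv_fold_``, ``cv_auc_`` (pooled out-of-fold AUC of
    the fused score), ``classes_``.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        cv: int = 10,
        weight_step: float = 0.05,
        sp_targets: tuple = DEFAULT_SP_TARGETS,
        default_level: str = "moderate",
        random_state: int | None = 0,
    ):
        self.n_trees = n_trees
        self.cv = cv
        self.weight_step = weight_step
        self.sp_targets = sp_targets
        self.default_level = default_level
        self.random_state = random_state

    # -- helpers --
    @staticmethod
    def _check_X(X: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        if not isinstance(X, Mapping) or not X:
            raise EnsembleError(
                "X must be a non-empty mapping {encoder_name: feature matrix}"
            )
        names = [n for n in ENCODER_ORDER if n in X]
        unknown = set(X) - set(ENCODER_ORDER)
        if unknown:
            raise EnsembleError(f"unknown encoder(s) {sorted(unknown)}")
        mats = {n: np.asarray(X[n], dtype=float) for n in names}
        sizes = {m.shape[0] for m in mats.values()}
        if len(sizes) != 1:
            raise EnsembleError("encoder matrices disagree on peptide count")
        return mats

    def _seed(self, salt: int) -> int:
        base = 0 if self.random_state is None else int(self.random_state)
        return (base * 7919 + salt) % (2**31 - 1)

    # -- estimator API --
    def fit(self, X: Mapping[str, np.ndarray], y, refit: bool = True):
        mats = self._check_X(X)
        y = np.asarray(y, dtype=int)
        n = next(iter(mats.values())).shape[0]
        if y.shape[0] != n:
            raise EnsembleError("labels length does not match feature matrices")
        classes, counts = np.unique(y, return_counts=True)
        if not np.array_equal(classes, [0, 1]):
            raise EnsembleError("labels must be binary 0/1 with both classes present")
        if counts.min() < self.cv:
            raise EnsembleError(
                f"each class needs >= cv={self.cv} samples (got {counts.min()})"
            )
        self.encoder_names_ = tuple(mats.keys())
        self.classes_ = np.array([0, 1])

        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self._seed(0)
        )
        oof = {name: np.full(n, np.nan) for name in self.encoder_names_}
        fold_id = np.full(n, -1, dtype=int)
        splits = list(skf.split(np.zeros(n), y))
        for f, (tr, te) in enumerate(splits):
            fold_id[te] = f
            for e, name in enumerate(self.encoder_names_):
                cfg = ForestConfig(n_trees=self.n_trees, seed=self._seed(1000 + 31 * f + e))
                model = train_forest(mats[name][tr], y[tr], cfg)
                oof[name][te] = forest_scores(model, mats[name][te])
        S = np.column_stack([oof[name] for name in self.encoder_names_])
        self.weights_, self.cv_auc_ = grid_search_weights(
            S, y, step=self.weight_step, encoder_names=self.encoder_names_
        )
        w = self.weights_.as_dict()
        combined = S @ np.array([w[name] for name in self.encoder_names_])
        self.thresholds_ = calibrate_thresholds(
            combined, y, sp_targets=self.sp_targets
        )
        self.cv_scores_ = pd.DataFrame(oof)
        self.cv_scores_["combined"] = combined
        self.cv_fold_ = fold_id
        self.forests_ = {}
        if refit:
            for e, name in enumerate(self.encoder_names_):
                cfg = ForestConfig(n_trees=self.n_trees, seed=self._seed(500 + e))
                self.forests_[name] = train_forest(mats[name], y, cfg)
        return self

    def encoder_scores(self, X: Mapping[str, np.ndarray]) -> pd.DataFrame:
        """Per-encoder forest scores for new peptides (NaN for absent encoders)."""
        if not self.forests_:
            raise EnsembleError("classifier was fitted with refit=False")
        mats = self._check_X(X)
        n = next(iter(mats.values())).shape[0]
        out = pd.DataFrame(index=range(n))
        for name in ENCODER_ORDER:
            if name in self.forests_ and name in mats:
                model = self.forests_[name]
                if mats[name].shape[1] != model.n_features_in_:
                    raise EnsembleError(
                        f"{name}: encoding has {mats[name].shape[1]} dims but the "
                        f"model expects {model.n_features_in_}"
                    )
                out[name] = forest_scores(model, mats[name])
            elif name in self.encoder_names_:
                raise EnsembleError(f"encoder {name!r} was trained but is missing from X")
            else:
                out[name] = np.nan
        return out

    def decision_function(self, X: Mapping[str, np.ndarray]) -> np.ndarray:
        scores = self.encoder_scores(X)
        return np.array(
            [
                combine_scores(row, self.weights_)
                for row in scores[list(ENCODER_ORDER)].to_numpy()
            ]
        )

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return np.column_stack([1 - s, s])

    def predict(self, X, level: str | None = None) -> np.ndarray:
        level = level or self.default_level
        cut = self.thresholds_.cutoff(level)
        return (self.decision_function(X) >= cut).astype(int)

    def predict_table(self, X, ids: Sequence[str] | None = None) -> pd.DataFrame:
        """One row per peptide: encoder scores, combined score, per-level calls."""
        scores = self.encoder_scores(X)
        combined = np.array(
            [
                combine_scores(row, self.weights_)
                for row in scores[list(ENCODER_ORDER)].to_numpy()
            ]
        )
        table = scores.copy()
        table.insert(0, "id", list(ids) if ids is not None else list(range(len(scores))))
        table["combined"] = combined
        for level in self.thresholds_.levels:
            table[f"call_{level}"] = combined >= self.thresholds_.cutoff(level)
        return table


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

def save_bundle(path, classifier: AIPEnsembleClassifier, extra: dict | None = None) -> None:
    """Serialize a fitted classifier (forests, weights, thresholds, configs)."""
    payload = {"format": "aipkit-bundle-1", "classifier": classifier}
    if extra:
        payload.update(extra)
    joblib.dump(payload, path)


def load_bundle(path) -> dict:
    payload = joblib.load(path)
    if payload.get("format") != "aipkit-bundle-1":
        raise EnsembleError(f"{path} is not an aipkit model bundle")
    return payload
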