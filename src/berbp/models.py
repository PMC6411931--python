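"""Specific and general Random-Forest binding classifiers.

``VoteForest`` is a thin bagging ensemble over decision trees that keeps
explicit out-of-bag (OOB) bookkeeping: every tree stores which training
rows its bootstrap excluded, so OOB vote fractions, OOB AUC and OOB
permutation importance are computed exactly rather than approximated.
Vote fractions are the fraction of trees voting positive, matching the
votes semantics of classical Random-Forest implementations.

Specific models train on raw features of one PWM; the general model
pools z-standardized features from several PWMs with a configurable
(default 1:2) positive-to-negative ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from berbp.evaluation import roc_auc
from berbp.features import FEATURE_NAMES, FeatureVector
from berbp.io_formats import PredictionRecord
from berbp.standardization import BackgroundStats

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
DEFAULT_MTRY = 6  # floor(sqrt(40)), the classification default of randomForest
DEFAULT_CALL_THRESHOLD = 0.5


class StandardizationError(ValueError):
    """Raw and standardized feature spaces were mixed."""


class NotFittedError(RuntimeError):
    pass


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels for one PWM."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    pwm_id: str
    standardized: bool = False
    stats_fingerprint: str | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must be (n, {len(FEATURE_NAMES)})")
        if y.shape != (X.shape[0],) or len(self.ids) != X.shape[0]:
            raise ValueError("X, y and ids must agree in length")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if not np.isfinite(X).all():
            raise ValueError("feature matrix contains non-finite values")
        self.X, self.y = X, y

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())


class VoteForest:
    """Bagged decision trees with explicit OOB bookkeeping.

    Each tree is fit on a bootstrap sample (n draws with replacement,
    seeded); the complement rows are that tree's OOB set.  Fully
    deterministic given (data, hyperparameters, seed).
    """

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        mtry: int = DEFAULT_MTRY,
        seed: int = 0,
        min_samples_leaf: int = 1,
    ) -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self.trees_: list[DecisionTreeClassifier] | None = None
        self.oob_masks_: np.ndarray | None = None  # (n_trees, n) True = row OOB
        self.X_: np.ndarray | None = None
        self.y_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VoteForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.RandomState(self.seed)
        self.trees_ = []
        self.oob_masks_ = np.zeros((self.n_trees, n), dtype=bool)
        mtry = min(self.mtry, X.shape[1])
        for t in range(self.n_trees):
            boot = rng.randint(0, n, n)
            tree = DecisionTreeClassifier(
                max_features=mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=rng.randint(np.iinfo(np.int32).max),
            )
            tree.fit(X[boot], y[boot])
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            self.oob_masks_[t] = oob
            self.trees_.append(tree)
        self.X_, self.y_ = X, y
        return self

    def _check_fitted(self) -> None:
        if self.trees_ is None:
            raise NotFittedError("forest has not been fit")

    def _tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n) matrix of per-tree positive-class votes."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        votes = np.empty((len(self.trees_), X.shape[0]), dtype=np.int8)
        for t, tree in enumerate(self.trees_):
            pred = tree.predict(X)
            if tree.n_classes_ == 1:  # single-class bootstrap (tiny n only)
                pred = np.full(X.shape[0], tree.classes_[0])
            votes[t] = pred
        return votes

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting positive per row, in [0, 1]."""
        return self._tree_votes(X).mean(axis=0)

    def oob_vote_fractions(self) -> np.ndarray:
        """Per-training-row vote fraction using only OOB trees.

        Rows that were in every bootstrap (possible at tiny n_trees) get
        NaN and must be excluded from downstream metrics.
        """
        self._check_fitted()
        votes = self._tree_votes(self.X_).astype(float)
        counts = self.oob_masks_.sum(axis=0).astype(float)
        sums = (votes * self.oob_masks_).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sums / counts
        out[counts == 0] = np.nan
        return out


@dataclass
class BindingModel:
    """A trained forest plus the provenance needed to use it safely."""

    model_id: str
    kind: str  # "specific" | "general"
    pwm_ids: tuple[str, ...]
    forest: VoteForest
    n_trees: int
    mtry: int
    seed: int
    standardized: bool
    backend_mode: str = "mfe"
    n_pos: int = 0
    n_neg: int = 0
    oob_auc: float | None = None


def _oob_auc(forest: VoteForest) -> float | None:
    scores = forest.oob_vote_fractions()
    keep = ~np.isnan(scores)
    y = forest.y_[keep]
    if np.unique(y).size < 2:
        return None
    return roc_auc(y, scores[keep])


def train_specific(
    data: LabeledDataset,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
    backend_mode: str = "mfe",
    model_id: str | None = None,
) -> BindingModel:
    """Train a per-PWM forest on raw (unstandardized) features."""
    if data.n_pos == 0 or data.n_neg == 0:
        raise ValueError("training data must contain both classes")
    if data.n_pos < 10 or data.n_neg < 10:
        raise ValueError(
            f"need >= 10 rows per class, got {data.n_pos} pos / {data.n_neg} neg"
        )
    forest = VoteForest(n_trees=n_trees, mtry=mtry, seed=seed).fit(data.X, data.y)
    model = BindingModel(
        model_id=model_id or f"specific:{data.pwm_id}",
        kind="specific",
        pwm_ids=(data.pwm_id,),
        forest=forest,
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
        standardized=data.standardized,
        backend_mode=backend_mode,
        n_pos=data.n_pos,
        n_neg=data.n_neg,
        oob_auc=_oob_auc(forest),
    )
    logger.info(
        "trained %s: %d pos / %d neg, %d trees, seed %d, OOB AUC %s",
        model.model_id, model.n_pos, model.n_neg, n_trees, seed, model.oob_auc,
    )
    return model


def train_general(
    datasets: Sequence[LabeledDataset],
    stats: dict[str, BackgroundStats],
    neg_ratio: float = 2.0,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
    backend_mode: str = "mfe",
    model_id: str = "general",
) -> BindingModel:
    """Pool standardized datasets from several PWMs into one forest.

    Positives are pooled in full; negatives are down/oversampled (seeded,
    without replacement when the pool allows) to ``neg_ratio`` times the
    positive count.  Every dataset must have been standardized with the
    exact background stats passed in — a mismatched fingerprint is an
    error, never a silent coercion.
    """
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be > 0")
    if len({d.pwm_id for d in datasets}) < 2:
        raise ValueError("general model requires datasets from >= 2 distinct PWMs")
    for d in datasets:
        if not d.standardized:
            raise StandardizationError(
                f"dataset for {d.pwm_id!r} is not standardized; the general "
                "model trains on z-transformed features only"
            )
        st = stats.get(d.pwm_id)
        if st is None:
            raise ValueError(f"no background stats supplied for PWM {d.pwm_id!r}")
        if d.stats_fingerprint != st.fingerprint:
            raise StandardizationError(
                f"dataset for {d.pwm_id!r} was standardized with different "
                "background stats than those supplied"
            )
    X_pos = np.vstack([d.X[d.y == 1] for d in datasets])
    X_neg_pool = np.vstack([d.X[d.y == 0] for d in datasets])
    n_pos = X_pos.shape[0]
    n_neg = int(round(neg_ratio * n_pos))
    rng = np.random.RandomState(seed)
    replace = n_neg > X_neg_pool.shape[0]
    pick = rng.choice(X_neg_pool.shape[0], size=n_neg, replace=replace)
    X = np.vstack([X_pos, X_neg_pool[pick]])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    forest = VoteForest(n_trees=n_trees, mtry=mtry, seed=seed).fit(X, y)
    model = BindingModel(
        model_id=model_id,
        kind="general",
        pwm_ids=tuple(sorted({d.pwm_id for d in datasets})),
        forest=forest,
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
        standardized=True,
        backend_mode=backend_mode,
        n_pos=n_pos,
        n_neg=n_neg,
        oob_auc=_oob_auc(forest),
    )
    logger.info(
        "trained %s over %d PWMs: %d pos / %d neg (ratio %.2g), seed %d, "
        "negatives sampled %s replacement",
        model.model_id, len(model.pwm_ids), n_pos, n_neg, neg_ratio, seed,
        "with" if replace else "without",
    )
    return model


def oob_scores(model: BindingModel) -> np.ndarray:
    """Per-training-row OOB vote fractions (NaN = row never out-of-bag)."""
    if model.forest.oob_masks_ is None:
        raise ValueError("model retains no out-of-bag bookkeeping")
    return model.forest.oob_vote_fractions()


def predict(
    model: BindingModel,
    features: Sequence[FeatureVector],
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
) -> list[PredictionRecord]:
    """Score feature vectors; a binding call is vote_fraction >= threshold.

    The standardization state of every vector must match the model's —
    mixing raw features into a standardized model (or vice versa) raises.
    """
    for fv in features:
        if fv.standardized != model.standardized:
            raise StandardizationError(
                f"model {model.model_id!r} expects "
                f"{'standardized' if model.standardized else 'raw'} features, "
                f"but {fv.seq_id!r} is {'standardized' if fv.standardized else 'raw'}"
            )
    if not features:
        return []
    X = np.stack([fv.values for fv in features])
    fractions = model.forest.vote_fractions(X)
    return [
        PredictionRecord(
            seq_id=fv.seq_id,
            pwm_id=fv.pwm_id,
            model_id=model.model_id,
            vote_fraction=float(f),
            binding_call=bool(f >= call_threshold),
            best_site_start=fv.best_site_start,
            best_site_score=fv.best_site_score,
        )
        for fv, f in zip(features, fractions)
    ]


def feature_importance(model: BindingModel, seed: int = 0) -> list[tuple[str, float]]:
    """OOB permutation importance, ranked descending (ties by column order).

    For each feature, the column is permuted once (seeded) and the mean
    per-tree decrease in OOB accuracy is recorded.
    """
    forest = model.forest
    if forest.oob_masks_ is None or forest.X_ is None:
        raise ValueError("model retains no out-of-bag bookkeeping")
    X, y = forest.X_, forest.y_
    n = X.shape[0]
    rng = np.random.RandomState(seed)
    base_votes = forest._tree_votes(X)
    importances = np.zeros(len(FEATURE_NAMES))
    for j in range(len(FEATURE_NAMES)):
        perm = rng.permutation(n)
        Xp = X.copy()
        Xp[:, j] = X[perm, j]
        perm_votes = forest._tree_votes(Xp)
        deltas = []
        for t in range(forest.n_trees):
            oob = forest.oob_masks_[t]
            if not oob.any():
                continue
            acc0 = (base_votes[t, oob] == y[oob]).mean()
            acc1 = (perm_votes[t, oob] == y[oob]).mean()
            deltas.append(acc0 - acc1)
        importances[j] = float(np.mean(deltas)) if deltas else 0.0
    order = np.lexsort((np.arange(len(FEATURE_NAMES)), -importances))
    return [(FEATURE_NAMES[j], float(importances[j])) for j in order]


def cross_predict(model: BindingModel, data: LabeledDataset) -> float:
    """AUC of one model's vote fractions on another PWM's labeled data.

    Transfer across PWMs is only meaningful in the standardized feature
    space, so both sides must be standardized.
    """
    if not model.standardized or not data.standardized:
        raise StandardizationError(
            "cross-PWM prediction requires standardized features on both sides"
        )
    scores = model.forest.vote_fractions(data.X)
    return roc_auc(data.y, scores)
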