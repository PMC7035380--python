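"""Random-Forest classification of epochs: normalization, grid tuning by
5-fold cross-validation on macro F-measure, training, and voting prediction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES


@dataclass(frozen=True)
class RFGrid:
    """Hyperparameter candidates for the forest.

    The default grid spans 6 x 5 x 6 = 180 combinations; ``n_predictors``
    includes round(sqrt(54)) = 7, the usual per-split feature-subset size.
    """

    n_trees: tuple[int, ...] = (10, 20, 50, 100, 200, 500)
    n_predictors: tuple[int, ...] = (4, 7, 10, 15, 20)
    min_leaf: tuple[int, ...] = (1, 3, 5, 10, 20, 50)

    @property
    def size(self) -> int:
        return len(self.n_trees) * len(self.n_predictors) * len(self.min_leaf)

    def combinations(self):
        """(n_trees, n_predictors, min_leaf) tuples in deterministic order."""
        return list(itertools.product(self.n_trees, self.n_predictors, self.min_leaf))


def desk_grid() -> RFGrid:
    """12-combination grid for desk-scale experiments."""
    return RFGrid(n_trees=(20, 50), n_predictors=(4, 7), min_leaf=(1, 3, 5))


@dataclass
class NormStats:
    """Per-feature training mean/SD (sample SD, n-1); constant features are
    flagged and mapped to 0."""

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES


def fit_norm(train: np.ndarray) -> NormStats:
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training epochs to normalize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    constant = sd == 0
    return NormStats(mean=mean, sd=np.where(constant, 1.0, sd), constant=constant)


def apply_norm(x: np.ndarray, stats: NormStats) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    z = (x - stats.mean) / stats.sd
    z[:, stats.constant] = 0.0
    return z


def normalize(
    train: np.ndarray, apply_to: Optional[np.ndarray] = None
) -> tuple[np.ndarray, Optional[np.ndarray], NormStats]:
    """Z-score the training matrix and map ``apply_to`` with the training
    statistics (test vectors are expressed in the training feature space)."""
    stats = fit_norm(train)
    train_z = apply_norm(train, stats)
    other_z = apply_norm(apply_to, stats) if apply_to is not None else None
    return train_z, other_z, stats


def _make_forest(params: tuple[int, int, int], n_features: int, seed) -> RandomForestClassifier:
    n_trees, n_pred, min_leaf = params
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(n_pred, n_features),
        min_samples_leaf=min_leaf,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )


def tune_cv(
    X: np.ndarray,
    y: Sequence[str],
    grid: RFGrid,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[tuple[int, int, int], float]:
    """Pick the grid combination with the highest mean macro F-measure across
    stratified k folds; ties break toward fewer trees, then larger min_leaf.

    Returns (params, best mean F).  Normalization statistics are fitted on
    each fold's training part only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"each class needs >= {k_folds} epochs for {k_folds}-fold CV "
            f"(min count {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % (2**31))
    folds = list(skf.split(X, y))
    best_key = None
    best = None
    for params in grid.combinations():
        scores = []
        for tr, va in folds:
            stats = fit_norm(X[tr])
            clf = _make_forest(params, X.shape[1], seed)
            clf.fit(apply_norm(X[tr], stats), y[tr])
            pred = clf.predict(apply_norm(X[va], stats))
            scores.append(f1_score(y[va], pred, average="macro", zero_division=0))
        mean_f = float(np.mean(scores))
        key = (-mean_f, params[0], -params[2], params[1])
        if best_key is None or key < best_key:
            best_key, best = key, (params, mean_f)
    return best


@dataclass
class TrainedModel:
    """A fitted forest plus everything prediction depends on."""

    forest: RandomForestClassifier
    params: tuple[int, int, int]
    norm: NormStats
    classes: tuple[str, ...]
    cv_f_measure: float
    seed: int


def train(
    X: np.ndarray,
    y: Sequence[str],
    params: tuple[int, int, int],
    seed: int = 0,
    cv_f_measure: float = float("nan"),
) -> TrainedModel:
    """Fit normalization on the full training set, then the bagged forest."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    stats = fit_norm(X)
    clf = _make_forest(params, X.shape[1], seed)
    clf.fit(apply_norm(X, stats), y)
    return TrainedModel(
        forest=clf,
        params=tuple(params),
        norm=stats,
        classes=tuple(clf.classes_),
        cv_f_measure=float(cv_f_measure),
        seed=int(seed),
    )


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and winning vote fractions for raw feature rows.

    Vote ties break by the model's fixed (lexicographic) class order.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.array([], dtype=object), np.array([])
    if X.shape[1] != len(model.norm.mean):
        raise ValueError(
            f"feature count {X.shape[1]} != model's {len(model.norm.mean)}"
        )
    proba = model.forest.predict_proba(apply_norm(X, model.norm))
    idx = np.argmax(proba, axis=1)  # first (lexicographically lowest) class wins ties
    labels = np.asarray(model.classes, dtype=object)[idx]
    return labels, proba[np.arange(len(idx)), idx]


def tune_and_train(X, y, grid: RFGrid, k_folds: int = 5, seed: int = 0) -> TrainedModel:
    params, score = tune_cv(X, y, grid, k_folds=k_folds, seed=seed)
    return train(X, y, params, seed=seed, cv_f_measure=score)


def split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and label vector from a canonical feature table."""
    return table[list(FEATURE_NAMES)].to_numpy(dtype=float), table["class_label"].to_numpy()
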