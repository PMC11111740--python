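"""Gradient-boosted tree classifier over phage-host pair features.

The estimator follows scikit-learn conventions (``fit`` / ``predict_proba``
/ ``get_params``), wraps an XGBoost ensemble, and optionally tunes the
three hyperparameters that matter for this problem — tree depth, learning
rate and number of boosting rounds — over a fixed 4x3x3 grid by stratified
five-fold cross-validation on ROC AUC.

Determinism contract: for a fixed seed (and single-threaded training) the
tuner and the fitted ensemble are reproducible, and tuning is invariant to
row shuffling because folds are assigned after sorting rows into a
canonical order derived from their content, not their input position.
"""

from __future__ import annotations

import hashlib
from itertools import product
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from xgboost import XGBClassifier

#: hyperparameter grid searched by the tuner: 4 x 3 x 3 = 36 configurations
DEFAULT_GRID: dict[str, tuple] = {
    "max_depth": (3, 5, 7, 9),
    "learning_rate": (0.2, 0.3, 0.4),
    "n_estimators": (250, 500, 750),
}


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row permutation determined by row content only (digest sort)."""
    digests = [
        hashlib.blake2b(
            np.ascontiguousarray(X[i], dtype=np.float64).tobytes()
            + bytes([int(y[i])]),
            digest_size=16,
        ).digest()
        for i in range(len(y))
    ]
    return np.argsort(np.array([d.hex() for d in digests]), kind="stable")


def _make_booster(max_depth, learning_rate, n_estimators, seed,
                  scale_pos_weight=None) -> XGBClassifier:
    return XGBClassifier(
        max_depth=int(max_depth),
        learning_rate=float(learning_rate),
        n_estimators=int(n_estimators),
        random_state=int(seed),
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
        scale_pos_weight=scale_pos_weight,
    )


def tune_hyperparameters(
    features: np.ndarray,
    labels: np.ndarray,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    n_folds: int = 5,
    scale_pos_weight: float | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Grid search by stratified k-fold cross-validated ROC AUC.

    Every grid point is evaluated (36 for the default grid).  Ties on mean
    AUC are broken toward the cheaper model: smaller n_estimators, then
    smaller max_depth, then smaller learning_rate.

    Returns (best_params, results) where results has one row per
    configuration with its mean CV AUC.
    """
    X, y = check_X_y(np.asarray(features, dtype=np.float64), labels)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to tune")
    if len(np.unique(y)) < 2:
        raise ValueError("tuning requires both classes present")
    grid = dict(grid or DEFAULT_GRID)

    order = _canonical_order(X, y)
    Xs, ys = X[order], y[order]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xs, ys))

    records = []
    for depth, lr, n_est in product(
        grid["max_depth"], grid["learning_rate"], grid["n_estimators"]
    ):
        aucs = []
        for train_idx, test_idx in folds:
            booster = _make_booster(depth, lr, n_est, seed, scale_pos_weight)
            booster.fit(Xs[train_idx], ys[train_idx])
            scores = booster.predict_proba(Xs[test_idx])[:, 1]
            aucs.append(roc_auc_score(ys[test_idx], scores))
        records.append(
            {"max_depth": depth, "learning_rate": lr, "n_estimators": n_est,
             "mean_cv_auc": float(np.mean(aucs))}
        )
    results = pd.DataFrame(records)
    best = results.sort_values(
        by=["mean_cv_auc", "n_estimators", "max_depth", "learning_rate"],
        ascending=[False, True, True, True],
        kind="stable",
    ).iloc[0]
    best_params = {
        "max_depth": int(best["max_depth"]),
        "learning_rate": float(best["learning_rate"]),
        "n_estimators": int(best["n_estimators"]),
    }
    return best_params, results


class PhageHostClassifier(ClassifierMixin, BaseEstimator):
    """Boosted-tree binary classifier for phage-host pair features.

    Defaults to the hyperparameters found optimal for this problem
    (max_depth=7, learning_rate=0.3, n_estimators=250); with ``tune=True``
    the grid is searched on the training data first.

    Parameters
    ----------
    max_depth, learning_rate, n_estimators : booster hyperparameters,
        used directly when ``tune`` is False.
    tune : run the stratified 5-fold grid search during ``fit``.
    grid : grid to search (defaults to :data:`DEFAULT_GRID`).
    scale_pos_weight : optional positive-class weight for the ~3% positive
        imbalance; None (no reweighting) by default.
    random_state : seed propagated to fold assignment and tree training.

    Attributes
    ----------
    model_ : the fitted XGBoost ensemble.
    best_params_ : hyperparameters actually used.
    cv_results_ : tuning table (only when ``tune=True``).
    metadata_ : dict with seed, feature dimension and class counts.
    """

    def __init__(
        self,
        max_depth: int = 7,
        learning_rate: float = 0.3,
        n_estimators: int = 250,
        tune: bool = False,
        grid: Mapping[str, Sequence] | None = None,
        scale_pos_weight: float | None = None,
        random_state: int = 0,
    ):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.tune = tune
        self.grid = grid
        self.scale_pos_weight = scale_pos_weight
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=np.float64), y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        self.classes_ = classes
        if self.tune:
            self.best_params_, self.cv_results_ = tune_hyperparameters(
                X, y, grid=self.grid, seed=self.random_state,
                scale_pos_weight=self.scale_pos_weight,
            )
        else:
            self.best_params_ = {
                "max_depth": self.max_depth,
                "learning_rate": self.learning_rate,
                "n_estimators": self.n_estimators,
            }
        self.model_ = _make_booster(
            seed=self.random_state, scale_pos_weight=self.scale_pos_weight,
            **self.best_params_,
        )
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.metadata_ = {
            "seed": self.random_state,
            "feature_dim": int(X.shape[1]),
            "n_pos": int((y == 1).sum()),
            "n_neg": int((y == 0).sum()),
            "params": dict(self.best_params_),
        }
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[0] == 0:
            return X.reshape(0, self.n_features_in_)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension "
                f"{self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        return self.model_.predict_proba(X)

    def predict_scores(self, X) -> np.ndarray:
        """Interaction scores in [0,1], one per row, order-preserving."""
        proba = self.predict_proba(X)
        return proba[:, 1] if len(proba) else np.empty(0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)

    def save(self, path) -> None:
        """Serialize the fitted estimator (params + metadata + ensemble)."""
        check_is_fitted(self, "model_")
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "PhageHostClassifier":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a {cls.__name__}")
        return model


def train(
    features: np.ndarray,
    labels: np.ndarray,
    params: Mapping | None = None,
    seed: int = 0,
    **kwargs,
) -> PhageHostClassifier:
    """Fit a classifier with explicit hyperparameters (tuned defaults)."""
    return PhageHostClassifier(
        **(dict(params) if params else {}), random_state=seed, **kwargs
    ).fit(features, labels)


def predict_scores(model: PhageHostClassifier, features: np.ndarray) -> np.ndarray:
    return model.predict_scores(features)
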