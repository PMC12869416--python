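"""Stratified out-of-fold risk scoring with pluggable classifiers.

Every cohort member receives exactly one risk score, produced by a
model that never saw the member's fold during training. The test folds
then serve as hypothetical general populations for the enrichment
evaluation, so the out-of-fold discipline is what makes the lift
numbers honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .features import FeatureMatrix

# Hyperparameters sized for synthetic populations of a few thousand
# members; recorded here so every scored cohort carries its provenance.
DEFAULT_XGB_PARAMS: dict[str, Any] = {
    "n_estimators": 150,
    "max_depth": 3,
    "learning_rate": 0.1,
    "tree_method": "hist",
    "n_jobs": 1,
    "reg_lambda": 1.0,
    "eval_metric": "logloss",
}
DEFAULT_LOGISTIC_PARAMS: dict[str, Any] = {"C": 1.0, "max_iter": 2000}


def _make_xgboost(params: dict[str, Any], seed: int):
    from xgboost import XGBClassifier

    merged = {**DEFAULT_XGB_PARAMS, **params}
    return XGBClassifier(random_state=seed, **merged)


def _make_logistic(params: dict[str, Any], seed: int):
    merged = {**DEFAULT_LOGISTIC_PARAMS, **params}
    return LogisticRegression(random_state=seed, **merged)


MODEL_REGISTRY: dict[str, Callable[[dict[str, Any], int], Any]] = {
    "xgboost": _make_xgboost,
    "logistic": _make_logistic,
}


@dataclass(frozen=True)
class ModelSpec:
    """Names a registered classifier backend plus hyperparameter overrides."""

    name: str = "xgboost"
    params: dict[str, Any] = field(default_factory=dict)

    def build(self, seed: int):
        if self.name not in MODEL_REGISTRY:
            raise KeyError(
                f"unknown model backend {self.name!r}; registered backends: "
                f"{sorted(MODEL_REGISTRY)}"
            )
        return MODEL_REGISTRY[self.name](self.params, seed)


def make_folds(cohort: pd.DataFrame, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold ids in 1..k, one per cohort row.

    Cases and controls are shuffled separately with the given seed and
    dealt round-robin, so per-fold case and control counts differ by at
    most one from perfect stratification.
    """
    labels = cohort["label"].to_numpy()
    n_cases = int((labels == 1).sum())
    n_controls = int((labels == 0).sum())
    if n_cases < k or n_controls < k:
        raise ValueError(
            f"need at least k={k} cases and controls to stratify; got "
            f"{n_cases} cases, {n_controls} controls"
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=np.int64)
    for value in (1, 0):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        folds[idx] = 1 + np.arange(idx.size) % k
    return folds


def train_and_score(
    features: FeatureMatrix,
    labels: np.ndarray | pd.Series,
    folds: np.ndarray,
    model_spec: ModelSpec | str = "xgboost",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, Any]]:
    """Out-of-fold scores plus the fitted per-fold models.

    Fold ``f``'s members are scored by a model trained on all other
    folds. Returns a scored-cohort frame (person_id, label, fold_id,
    score) and the fitted model per fold, retained for attribution.
    """
    if isinstance(model_spec, str):
        model_spec = ModelSpec(model_spec)
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    X = features.X
    scores = np.full(X.shape[0], np.nan)
    models: dict[int, Any] = {}
    for f in np.unique(folds):
        train = folds != f
        test = ~train
        model = model_spec.build(seed)
        model.fit(X[train], labels[train])
        scores[test] = model.predict_proba(X[test])[:, 1]
        models[int(f)] = model
    scored = pd.DataFrame(
        {
            "person_id": features.person_ids,
            "label": labels,
            "fold_id": folds,
            "score": scores,
        }
    )
    return scored, models


def auroc(scores, labels) -> float:
    """Probability a random case outranks a random control (ties = ½)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


class OutOfFoldRiskScorer(BaseEstimator):
    """Sklearn-style estimator for stratified out-of-fold risk scoring.

    Parameters
    ----------
    model : str or ModelSpec, default "xgboost"
        Registered classifier backend.
    n_splits : int, default 5
        Number of stratified folds.
    random_state : int, default 0
        Seed for fold dealing and the classifier backends.

    Attributes
    ----------
    scored_ : DataFrame
        person_id, label, fold_id, out-of-fold score.
    models_ : dict[int, estimator]
        Fitted classifier per fold (trained on the other folds).
    fold_ids_ : ndarray
        Fold assignment per cohort row.
    oof_scores_ : ndarray
        Out-of-fold score per cohort row, in [0, 1].
    """

    def __init__(self, model="xgboost", n_splits: int = 5, random_state: int = 0):
        self.model = model
        self.n_splits = n_splits
        self.random_state = random_state

    def fit(self, features: FeatureMatrix, cohort: pd.DataFrame):
        folds = make_folds(cohort, k=self.n_splits, seed=self.random_state)
        scored, models = train_and_score(
            features,
            cohort["label"].to_numpy(),
            folds,
            self.model,
            seed=self.random_state,
        )
        self.fold_ids_ = folds
        self.models_ = models
        self.scored_ = scored
        self.oof_scores_ = scored["score"].to_numpy()
        return self

    def score(self, features: FeatureMatrix, cohort: pd.DataFrame) -> float:
        """Mean per-fold out-of-fold AUROC after :meth:`fit`."""
        del features, cohort
        per_fold = [
            auroc(g["score"], g["label"])
            for _, g in self.scored_.groupby("fold_id")
        ]
        return float(np.mean(per_fold))
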