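"""Transporter pIC50 regressors and direct cholestasis QSAR classifiers.

Each of the eight hepatic transporters (P-gp, BCRP, OATP1B1, OATP1B3,
MRP4, MRP2, BSEP, MRP3) gets a low-level regression model (LLM) mapping
Morgan fingerprints to pIC50. Four families are considered per task —
XGBoost, random forest, k-nearest neighbours (regression) or naive Bayes
(classification), and support vector machines with both linear and
radial kernels — each tuned by grid search with 5-fold CV (MAE for
regression, ROC AUC for classification), and the best family is kept.

The grid search is implemented explicitly (ParameterGrid over a fixed
KFold) so that the selection rule and its first-occurrence tie-break are
exactly specified and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import mean_absolute_error, roc_auc_score
from sklearn.model_selection import KFold, ParameterGrid, RepeatedKFold
from sklearn.naive_bayes import GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILY_ORDER_REGRESSION",
    "FAMILY_ORDER_CLASSIFICATION",
    "TrainedModel",
    "ActivityMatrix",
    "default_regression_grid",
    "default_classification_grid",
    "make_estimator",
    "grid_search_fit",
    "select_best_family",
    "repeated_cv_evaluate",
    "train_transporter_models",
    "build_activity_matrix",
    "train_direct_qsar",
    "direct_qsar_predict",
]

#: Fixed family order used for deterministic tie-breaks.
FAMILY_ORDER_REGRESSION = ("XGB", "RF", "KNN", "SVM")
FAMILY_ORDER_CLASSIFICATION = ("XGB", "RF", "NB", "SVM")


@dataclass
class TrainedModel:
    """A fitted estimator with its selection provenance."""

    family: str
    params: dict
    estimator: object
    task: str                      # "regression" | "classification"
    feature_block: str = "FP"      # "FP" | "PC"
    cv_score: float = float("nan")  # CV MAE (regression) or ROC AUC (classification)
    seed: int = 0

    def predict(self, X):
        return self.estimator.predict(X)

    def predict_scores(self, X):
        """Continuous classification scores in [0, 1]."""
        if self.task != "classification":
            raise ValueError("scores are defined for classifiers only")
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        from scipy.special import expit
        return expit(est.decision_function(X))


def default_regression_grid(family: str) -> dict:
    """Small default hyperparameter grids per regression family."""
    grids = {
        "XGB": {"n_estimators": [100, 300], "max_depth": [3, 6],
                "learning_rate": [0.1]},
        "RF": {"n_estimators": [200], "max_depth": [None, 10]},
        "KNN": {"n_neighbors": [1, 3, 5], "weights": ["uniform", "distance"]},
        # epsilon well below typical assay precision so the insensitive
        # tube does not bias pIC50 fits
        "SVM": {"kernel": ["linear", "rbf"], "C": [1.0, 10.0],
                "epsilon": [0.1, 0.01]},
    }
    return grids[family]


def default_classification_grid(family: str) -> dict:
    grids = {
        "XGB": {"n_estimators": [100, 300], "max_depth": [3, 6],
                "learning_rate": [0.1]},
        "RF": {"n_estimators": [200], "max_depth": [None, 10]},
        "NB": {},  # MNB/GNB have no tuned hyperparameters here
        "SVM": {"kernel": ["linear", "rbf"], "C": [1.0, 10.0]},
    }
    return grids[family]


def make_estimator(family: str, task: str, params: dict, seed: int,
                   feature_block: str = "FP"):
    """Instantiate the base estimator for a (family, task) pair.

    Naive Bayes is multinomial for fingerprint features and Gaussian for
    physicochemical descriptors.
    """
    if task == "regression":
        if family == "XGB":
            return XGBRegressor(random_state=seed, n_jobs=1,
                                verbosity=0, **params)
        if family == "RF":
            return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        if family == "KNN":
            return KNeighborsRegressor(**params)
        if family == "SVM":
            return SVR(**params)
    elif task == "classification":
        if family == "XGB":
            return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                                 eval_metric="logloss", **params)
        if family == "RF":
            return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        if family == "NB":
            return MultinomialNB(**params) if feature_block == "FP" \
                else GaussianNB(**params)
        if family == "SVM":
            return SVC(probability=True, random_state=seed, **params)
    raise ValueError(f"unknown family/task: {family}/{task}")


def _cv_score_one(estimator, X, y, splits, task) -> float:
    """Mean CV score over pre-computed splits (MAE or ROC AUC)."""
    scores = []
    for train_idx, test_idx in splits:
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        if task == "regression":
            scores.append(mean_absolute_error(y[test_idx],
                                              est.predict(X[test_idx])))
        else:
            if hasattr(est, "predict_proba"):
                s = est.predict_proba(X[test_idx])[:, 1]
            else:
                s = est.decision_function(X[test_idx])
            scores.append(roc_auc_score(y[test_idx], s))
    return float(np.mean(scores))


def grid_search_fit(X, y, family: str, task: str, seed: int = 0,
                    grid: dict | None = None, cv: int = 5,
                    feature_block: str = "FP") -> TrainedModel:
    """Grid search with k-fold CV; returns the refit best model.

    Regression selects the grid point minimizing CV mean absolute error;
    classification maximizes CV ROC AUC. All grid points are scored on
    identical folds; ties keep the first grid point in iteration order.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float if task == "regression" else int)
    if len(X) != len(y) or len(y) < 10:
        raise ValueError("need matched X/y with at least 10 samples")
    if task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("classification target is constant")
    if grid is None:
        grid = (default_regression_grid(family) if task == "regression"
                else default_classification_grid(family))
    if task == "regression" and family == "SVM" and "kernel" in grid:
        kernels = set(grid["kernel"])
        if not {"linear", "rbf"} <= kernels and len(kernels) > 1:
            logger.warning("SVM grid without both linear and rbf kernels")
    splitter = KFold(n_splits=cv, shuffle=True, random_state=seed)
    splits = list(splitter.split(X))
    best_params, best_score = None, None
    for params in ParameterGrid(grid):
        est = make_estimator(family, task, params, seed, feature_block)
        score = _cv_score_one(est, X, y, splits, task)
        better = (best_score is None
                  or (task == "regression" and score < best_score)
                  or (task == "classification" and score > best_score))
        if better:
            best_params, best_score = params, score
    final = make_estimator(family, task, best_params, seed, feature_block)
    final.fit(X, y)
    return TrainedModel(family=family, params=best_params, estimator=final,
                        task=task, feature_block=feature_block,
                        cv_score=best_score, seed=seed)


def select_best_family(candidates: Sequence[TrainedModel]) -> TrainedModel:
    """Pick argmin CV MAE (regression) or argmax CV AUC (classification).

    Ties break by the fixed family order XGB < RF < KNN/NB < SVM.
    """
    if not candidates:
        raise ValueError("no candidate models")
    task = candidates[0].task
    if any(c.task != task for c in candidates):
        raise ValueError("candidates mix tasks")
    order = (FAMILY_ORDER_REGRESSION if task == "regression"
             else FAMILY_ORDER_CLASSIFICATION)
    rank = {f: i for i, f in enumerate(order)}
    sign = 1.0 if task == "regression" else -1.0
    return min(candidates,
               key=lambda c: (sign * c.cv_score, rank.get(c.family, 99)))


def repeated_cv_evaluate(model_factory: Callable[[], object], X, y,
                         n_repeats: int = 20, k: int = 5, seed: int = 0,
                         task: str = "regression") -> pd.DataFrame:
    """Repeated k-fold CV scores of a model specification.

    Returns one row per (repeat, fold) with the fold score (MAE or ROC
    AUC); summarize with ``.score.mean()`` / ``.score.std()``. The fold
    assignment depends only on (seed, n_repeats, k, n).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float if task == "regression" else int)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not (2 <= k <= len(y)):
        raise ValueError(f"k must be in [2, {len(y)}]")
    splitter = RepeatedKFold(n_splits=k, n_repeats=n_repeats,
                             random_state=seed)
    rows = []
    for i, (train_idx, test_idx) in enumerate(splitter.split(X)):
        est = model_factory()
        est.fit(X[train_idx], y[train_idx])
        if task == "regression":
            score = mean_absolute_error(y[test_idx], est.predict(X[test_idx]))
        else:
            if hasattr(est, "predict_proba"):
                s = est.predict_proba(X[test_idx])[:, 1]
            else:
                s = est.decision_function(X[test_idx])
            score = roc_auc_score(y[test_idx], s)
        rows.append({"repeat": i // k, "fold": i % k, "score": float(score)})
    return pd.DataFrame(rows)


def train_transporter_models(activity: pd.DataFrame,
                             fingerprints: dict[str, np.ndarray],
                             families: Sequence[str] = FAMILY_ORDER_REGRESSION,
                             grids: dict[str, dict] | None = None,
                             seed: int = 0) -> dict[str, TrainedModel]:
    """Fit one best-family LLM per transporter from replicate rows.

    ``activity`` has columns compound_id, transporter, pic50 with every
    replicate kept as its own row; ``fingerprints`` maps compound_id to
    its feature vector. Each transporter's stochastic fits receive a seed
    derived from (seed, transporter).
    """
    models: dict[str, TrainedModel] = {}
    for transporter, sub in activity.groupby("transporter", sort=True):
        X = np.vstack([fingerprints[c] for c in sub["compound_id"]])
        y = sub["pic50"].to_numpy(dtype=float)
        t_seed = derive_seed(seed, "llm", transporter)
        candidates = []
        for family in families:
            grid = (grids or {}).get(family)
            candidates.append(grid_search_fit(
                X, y, family, "regression", seed=t_seed, grid=grid))
        models[transporter] = select_best_family(candidates)
        logger.info("LLM %s: %s %s (CV MAE %.3f)", transporter,
                    models[transporter].family, models[transporter].params,
                    models[transporter].cv_score)
    return models


@dataclass
class ActivityMatrix:
    """Compounds x transporters pIC50 with per-cell provenance.

    Provenance is "experimental_mean" for cells backed by measured
    replicates and "predicted" for LLM-filled cells.
    """

    compound_ids: list[str]
    transporters: list[str]
    values: np.ndarray
    provenance: np.ndarray
    failed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.compound_ids), len(self.transporters))
        if self.values.shape != expected:
            raise ValueError("activity matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity matrix must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids,
                            columns=self.transporters)


def build_activity_matrix(compound_ids: Sequence[str],
                          fingerprints: dict[str, np.ndarray],
                          models: dict[str, TrainedModel],
                          experimental_lookup: dict | None = None
                          ) -> ActivityMatrix:
    """Predict the full pIC50 matrix, overriding with experimental means.

    A cell ``(compound, transporter)`` present in ``experimental_lookup``
    takes the mean of the measured replicates (provenance
    "experimental_mean"); everything else is the LLM prediction.
    Compounds lacking a feature vector are excluded and reported in
    ``failed_ids``.
    """
    experimental_lookup = experimental_lookup or {}
    transporters = sorted(models)
    ok_ids = [c for c in compound_ids if c in fingerprints]
    failed = [c for c in compound_ids if c not in fingerprints]
    if failed:
        logger.warning("featurization failed for %d compounds", len(failed))
    X = np.vstack([fingerprints[c] for c in ok_ids]) if ok_ids else \
        np.zeros((0, 2048))
    values = np.zeros((len(ok_ids), len(transporters)))
    prov = np.full(values.shape, "predicted", dtype=object)
    for j, tr in enumerate(transporters):
        if len(ok_ids):
            values[:, j] = models[tr].predict(X)
        for i, cid in enumerate(ok_ids):
            key = (cid, tr)
            if key in experimental_lookup:
                values[i, j] = experimental_lookup[key]
                prov[i, j] = "experimental_mean"
    return ActivityMatrix(ok_ids, transporters, values, prov, failed)


def train_direct_qsar(X, y, feature_block: str = "FP",
                      families: Sequence[str] = FAMILY_ORDER_CLASSIFICATION,
                      grids: dict[str, dict] | None = None,
                      seed: int = 0) -> TrainedModel:
    """Best-family direct cholestasis classifier on FP or PC features."""
    candidates = []
    for family in families:
        grid = (grids or {}).get(family)
        candidates.append(grid_search_fit(
            X, y, family, "classification", seed=derive_seed(seed, family),
            grid=grid, feature_block=feature_block))
    return select_best_family(candidates)


def direct_qsar_predict(model: TrainedModel, X, feature_block: str | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores in [0, 1] and labels at the 0.5 threshold."""
    if model.task != "classification":
        raise ValueError("direct QSAR prediction requires a classifier")
    if feature_block is not None and feature_block != model.feature_block:
        raise ValueError(
            f"feature block mismatch: model is {model.feature_block}, "
            f"input is {feature_block}")
    scores = model.predict_scores(np.asarray(X))
    return scores, (scores > 0.5).astype(int)
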