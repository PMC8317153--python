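"""Model training, greedy forward feature selection and evaluation.

Candidate learners are the ensemble-tree family (random forest, extremely
randomized trees, gradient boosting, extreme gradient boosting, AdaBoost)
plus k-nearest neighbours, each usable for binary activity classification
or per-cell-line GI50 regression. Feature selection is bottom-up greedy:
start from zero features, at each round score every remaining feature by
k-fold cross-validation when added to the current set, accept the best,
and keep the prefix with the best score overall.

Classification metrics (accuracy, precision, sensitivity, FPR, MCC, AUC)
are computed from closed forms here — AUC by the Mann-Whitney rank
statistic — so they can be cross-checked against independent
implementations. Regression uses Pearson, Kendall and RMSE, optionally
after trimming the 10% worst-predicted points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from xgboost import XGBClassifier, XGBRegressor

from .config import hash_mapping

N_ESTIMATORS = 300  # frozen ensemble size for all tree learners

LEARNERS = ("random_forest", "extra_trees", "gradient_boosting", "xgb", "knn", "adaboost")
TASKS = ("classification", "regression")


def make_estimator(task: str, learner: str, seed: int = 42, **overrides):
    """Instantiate a learner with the frozen default configuration."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from {LEARNERS}")
    clf = task == "classification"
    kw = {"random_state": seed}
    if learner == "random_forest":
        cls = RandomForestClassifier if clf else RandomForestRegressor
        kw.update(n_estimators=N_ESTIMATORS, n_jobs=1)
    elif learner == "extra_trees":
        cls = ExtraTreesClassifier if clf else ExtraTreesRegressor
        kw.update(n_estimators=N_ESTIMATORS, n_jobs=1)
    elif learner == "gradient_boosting":
        cls = GradientBoostingClassifier if clf else GradientBoostingRegressor
        kw.update(n_estimators=N_ESTIMATORS)
    elif learner == "xgb":
        cls = XGBClassifier if clf else XGBRegressor
        kw.update(n_estimators=N_ESTIMATORS, n_jobs=1, verbosity=0)
        if clf:
            kw.update(eval_metric="logloss")
    elif learner == "adaboost":
        cls = AdaBoostClassifier if clf else AdaBoostRegressor
        kw.update(n_estimators=N_ESTIMATORS)
    else:  # knn has neither ensemble size nor seed
        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        kw = {}
    kw.update(overrides)
    return cls(**kw)


def _check_matrix(X: pd.DataFrame) -> None:
    bad = X.columns[~np.isfinite(X.to_numpy(dtype=float)).all(axis=0)].tolist()
    if bad:
        raise ValueError(f"non-finite values in feature columns: {bad}")


# ---------------------------------------------------------------------------
# Metrics


def auc_rank(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic (ties get half credit)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    n1 = int((y_true == 1).sum())
    n0 = int((y_true == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(y_score)
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, tn, fp, fn


def evaluate_metrics(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    task: str,
    *,
    y_score: Sequence[float] | None = None,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Closed-form evaluation metrics for one prediction vector.

    Classification: ``y_pred`` may be scores (thresholded at 0.5 for the
    confusion-table metrics); pass ``y_score`` explicitly to use separate
    hard predictions and ranking scores. AUC on a single-class truth vector
    is undefined and reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-d vectors")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")

    if task == "classification":
        score = y_pred if y_score is None else np.asarray(y_score, dtype=float)
        hard = (y_pred >= threshold).astype(int)
        yt = y_true.astype(int)
        tp, tn, fp, fn = _confusion(yt, hard)
        n = tp + tn + fp + fn
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return {
            "accuracy": (tp + tn) / n,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "fpr": fp / (fp + tn) if fp + tn else 0.0,
            "mcc": (tp * tn - fp * fn) / denom if denom else 0.0,
            "auc": auc_rank(yt, score),
        }
    if task == "regression":
        pearson = stats.pearsonr(y_true, y_pred)[0] if np.std(y_pred) > 0 else float("nan")
        kendall = stats.kendalltau(y_true, y_pred)[0]
        rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
        return {"pearson": float(pearson), "kendall": float(kendall), "rmse": rmse}
    raise ValueError(f"unknown task {task!r}")


def trimmed_evaluation(
    y_true: Sequence[float], y_pred: Sequence[float], fraction: float = 0.10
) -> dict[str, float]:
    """Regression metrics after dropping the worst-predicted points.

    Removes the ceil(fraction * n) points with the largest absolute
    residual (ties broken by index order, lower index removed first) and
    recomputes Pearson/Kendall/RMSE on the rest. With n < 10 trimming is
    refused: untrimmed metrics are returned with ``trimmed = 0``.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_true)
    if n < 10:
        warnings.warn("n < 10: trimming refused, returning untrimmed metrics")
        out = evaluate_metrics(y_true, y_pred, "regression")
        out.update(trimmed=0.0, n_retained=float(n))
        return out
    n_drop = math.ceil(fraction * n)
    resid = np.abs(y_true - y_pred)
    drop = sorted(range(n), key=lambda i: (-resid[i], i))[:n_drop]
    keep = np.setdiff1d(np.arange(n), drop)
    out = evaluate_metrics(y_true[keep], y_pred[keep], "regression")
    out.update(trimmed=1.0, n_retained=float(len(keep)))
    return out


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class EvaluationReport:
    """Per-fold and pooled out-of-fold metrics for one model configuration."""

    task: str
    pooled: dict[str, float]
    per_fold: list[dict[str, float]]
    trimmed: dict[str, float] | None = None
    y_true: np.ndarray | None = field(default=None, repr=False)
    y_oof: np.ndarray | None = field(default=None, repr=False)


def _folds(y: np.ndarray, task: str, k: int, seed: int):
    if task == "classification":
        counts = np.unique(y, return_counts=True)[1]
        if counts.min() < k:
            raise ValueError(
                f"stratification failure: smallest class has {counts.min()} < k={k} members"
            )
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return KFold(n_splits=k, shuffle=True, random_state=seed)


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[float],
    task: str,
    learner: str = "random_forest",
    k: int = 10,
    seed: int = 42,
    estimator=None,
) -> EvaluationReport:
    """k-fold cross-validation with pooled out-of-fold metrics.

    Every sample is predicted exactly once by a model that never saw it;
    the headline metrics are computed on the pooled out-of-fold predictions
    (per-fold values are reported alongside). Classification folds are
    stratified.
    """
    _check_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(y) < k:
        raise ValueError(f"n={len(y)} < k={k}")
    base = estimator if estimator is not None else make_estimator(task, learner, seed)

    oof = np.full(len(y), np.nan)
    per_fold = []
    Xv = X.to_numpy(dtype=float)
    for train_idx, test_idx in _folds(y, task, k, seed).split(Xv, y):
        model = clone(base)
        model.fit(Xv[train_idx], y[train_idx])
        if task == "classification":
            pred = model.predict_proba(Xv[test_idx])[:, 1]
        else:
            pred = model.predict(Xv[test_idx])
        oof[test_idx] = pred
        per_fold.append(evaluate_metrics(y[test_idx], pred, task))

    pooled = evaluate_metrics(y, oof, task)
    trimmed = trimmed_evaluation(y, oof) if task == "regression" and len(y) >= 10 else None
    return EvaluationReport(
        task=task, pooled=pooled, per_fold=per_fold, trimmed=trimmed, y_true=y, y_oof=oof
    )


# ---------------------------------------------------------------------------
# Greedy forward feature selection


@dataclass
class SelectionTrace:
    """Path of a greedy forward selection run.

    ``steps`` records every accepted feature with the cross-validated
    metric after adding it; ``best_set`` is the prefix that achieved the
    best metric overall.
    """

    metric_name: str
    steps: list[tuple[str, float]]
    best_set: list[str]
    best_metric: float
    tolerance: float


def _cv_metric(X, y, task, base, metric, k, seed) -> float:
    folds = _folds(y, task, k, seed)
    oof = np.full(len(y), np.nan)
    for tr, te in folds.split(X, y):
        model = clone(base)
        model.fit(X[tr], y[tr])
        oof[te] = model.predict_proba(X[te])[:, 1] if task == "classification" else model.predict(X[te])
    if metric == "auc":
        return auc_rank(y.astype(int), oof)
    if metric == "pearson":
        return float(stats.pearsonr(y, oof)[0]) if np.std(oof) > 0 else -1.0
    raise ValueError(f"unknown selection metric {metric!r}")


def _univariate_scores(X: np.ndarray, y: np.ndarray, task: str) -> np.ndarray:
    if task == "classification":
        return np.array([abs(auc_rank(y.astype(int), X[:, j]) - 0.5) for j in range(X.shape[1])])
    sd = X.std(axis=0)
    out = np.zeros(X.shape[1])
    for j in np.where(sd > 0)[0]:
        out[j] = abs(stats.pearsonr(y, X[:, j])[0])
    return out


def greedy_select(
    X: pd.DataFrame,
    y: Sequence[float],
    task: str,
    learner: str = "random_forest",
    metric: str | None = None,
    cv_folds: int = 10,
    seed: int = 42,
    patience: int = 5,
    tolerance: float = 1e-4,
    candidate_pool: int | None = None,
    selection_params: dict | None = None,
    max_rounds: int | None = None,
) -> SelectionTrace:
    """Bottom-up greedy feature selection scored by cross-validation.

    Starting from zero features, each round evaluates every remaining
    candidate feature added to the current set by ``cv_folds``-fold CV and
    accepts the argmax (ties go to the earlier manifest column). The search
    stops after ``patience`` consecutive rounds whose best score does not
    beat the running best by more than ``tolerance``; the returned
    ``best_set`` is the globally best prefix, so the best-so-far metric
    sequence is non-decreasing by construction.

    ``candidate_pool`` optionally restricts the search to the top-scoring
    features by a univariate screen (rank AUC or |Pearson|), a scalability
    knob for wide matrices. ``selection_params`` overrides estimator
    parameters during the search only (e.g. a smaller ensemble), without
    touching the frozen defaults used for final training.
    """
    _check_matrix(X)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate target: single class")
    elif np.std(y) == 0:
        raise ValueError("degenerate target: constant")
    metric = metric or ("auc" if task == "classification" else "pearson")
    base = make_estimator(task, learner, seed, **(selection_params or {}))

    columns = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    candidates = list(range(len(columns)))
    if candidate_pool is not None and candidate_pool < len(candidates):
        scores = _univariate_scores(Xv, y, task)
        # stable sort keeps manifest order among exact ties
        top = np.argsort(-scores, kind="stable")[:candidate_pool]
        candidates = sorted(int(j) for j in top)

    current: list[int] = []
    steps: list[tuple[str, float]] = []
    best_metric = -np.inf
    best_len = 0
    stall = 0
    max_rounds = max_rounds if max_rounds is not None else len(candidates)
    for _ in range(max_rounds):
        if not candidates:
            break
        round_best, round_feat = -np.inf, None
        for j in candidates:
            m = _cv_metric(Xv[:, current + [j]], y, task, base, metric, cv_folds, seed)
            if m > round_best:  # strict: first-in-order wins ties
                round_best, round_feat = m, j
        current.append(round_feat)
        candidates.remove(round_feat)
        steps.append((columns[round_feat], float(round_best)))
        improved_enough = round_best > best_metric + tolerance
        if round_best > best_metric:
            best_metric = float(round_best)
            best_len = len(current)
        if improved_enough:
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return SelectionTrace(
        metric_name=metric,
        steps=steps,
        best_set=[columns[j] for j in current[:best_len]],
        best_metric=float(best_metric),
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# Model bundle


@dataclass
class ModelBundle:
    """A fitted estimator plus everything needed to reproduce its predictions."""

    task: str
    learner: str
    selected_features: list[str]
    seed: int
    model: object
    config_hash: str

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ValueError(f"feature matrix missing model features: {missing}")
        Xv = X[self.selected_features].to_numpy(dtype=float)
        if self.task == "classification":
            return self.model.predict_proba(Xv)[:, 1]
        return self.model.predict(Xv)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "ModelBundle":
        return joblib.load(path)


def train_model(
    X: pd.DataFrame,
    y: Sequence[float],
    task: str,
    learner: str = "random_forest",
    seed: int = 42,
    selected_features: list[str] | None = None,
) -> ModelBundle:
    """Fit a learner on (a feature subset of) the matrix and wrap it as a bundle."""
    features = selected_features if selected_features is not None else list(X.columns)
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValueError(f"selected features not in matrix: {missing}")
    Xs = X[features]
    _check_matrix(Xs)
    y = np.asarray(y, dtype=float)
    model = make_estimator(task, learner, seed)
    model.fit(Xs.to_numpy(dtype=float), y)
    cfg = {
        "task": task,
        "learner": learner,
        "seed": seed,
        "n_estimators": None if learner == "knn" else N_ESTIMATORS,
        "features": features,
    }
    return ModelBundle(
        task=task,
        learner=learner,
        selected_features=list(features),
        seed=seed,
        model=model,
        config_hash=hash_mapping(cfg),
    )
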