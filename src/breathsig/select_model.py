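"""Stratified splitting, resampling consensus feature selection and
cross-validated gradient-boosted classification.

Feature selection is a stability-selection scheme: two-thirds of the training
samples are redrawn without replacement over many iterations (1000 by default);
each iteration z-scores the subsample and fits an XGBoost classifier, and the
per-feature median importance across iterations ranks the features. The top-30
ranked features from forced and tidal maneuvers are intersected to form the
consensus set used for modeling (a top-percentile rule is available as an
alternative). Models are tuned by 5-fold stratified cross-validation on the
training split only; the held-out split (or leave-one-out aggregation for the
BDR endpoint) yields AUC, sensitivity, specificity, PPV and NPV at a 0.5
probability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from xgboost import XGBClassifier

DEFAULT_LEARNER_PARAMS = dict(
    n_estimators=50, max_depth=3, learning_rate=0.3, subsample=1.0,
    tree_method="hist", n_jobs=1, verbosity=0, eval_metric="logloss",
)

DEFAULT_PARAM_GRID = {
    "max_depth": [2, 3],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 100],
    "subsample": [0.8, 1.0],
}


class SplitError(ValueError):
    pass


class ConfigError(ValueError):
    pass


class CVError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Consensus feature selection across the two breathing maneuvers."""

    median_importance: dict[str, pd.Series]   # maneuver -> per-feature medians
    ranked_lists: dict[str, list]             # maneuver -> top_k feature ids
    top_k: int
    consensus_features: list
    n_iterations: int
    subsample_fraction: float
    seeds: list[int] = field(default_factory=list)


@dataclass
class ModelReport:
    endpoint: str
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    cv_scheme: str
    n_train: int
    n_test: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("endpoint", "auc", "sensitivity", "specificity", "ppv", "npv",
                 "threshold", "cv_scheme", "n_train", "n_test")}


def split_data(index, strata, train_fraction: float = 0.7, seed: int | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of sample ids.

    ``strata`` is an array-like of stratum labels (e.g. endpoint x maneuver)
    aligned with ``index``. Every stratum must have at least two members so
    both partitions can be populated.
    """
    index = np.asarray(index)
    strata = np.asarray(strata)
    if len(index) != len(strata):
        raise SplitError("index and strata must align")
    labels, counts = np.unique(strata, return_counts=True)
    singles = labels[counts < 2]
    if singles.size:
        raise SplitError(f"singleton strata cannot be split: {singles.tolist()}")
    train, test = train_test_split(
        index, train_size=train_fraction, stratify=strata, random_state=seed)
    return np.sort(train), np.sort(test)


def _importance_vector(model: XGBClassifier, columns, importance_type: str) -> np.ndarray:
    score = model.get_booster().get_score(importance_type=importance_type)
    return np.array([score.get(f"f{j}", 0.0) for j in range(len(columns))])


def resample_importance(X: pd.DataFrame, y, n_iter: int = 1000, frac: float = 2 / 3,
                        learner_params: dict | None = None, seed: int | None = None,
                        importance_type: str = "gain") -> pd.Series:
    """Per-feature median XGBoost importance over subsample iterations.

    Each iteration draws ``frac`` of the rows without replacement (redrawn if
    the subsample is single-class), z-scores the subsample, fits the learner,
    and extracts feature importances; the median across iterations is returned,
    indexed by the columns of ``X``.
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be at least 1")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ConfigError("need both classes present for importance resampling")
    params = {**DEFAULT_LEARNER_PARAMS, **(learner_params or {})}
    rng = np.random.default_rng(seed)
    n = len(X)
    size = max(2, int(round(frac * n)))
    Xv = X.to_numpy(dtype=float)
    importances = np.empty((n_iter, X.shape[1]))
    for it in range(n_iter):
        for _ in range(100):
            idx = rng.choice(n, size=size, replace=False)
            if len(np.unique(y[idx])) > 1:
                break
        else:
            raise CVError("could not draw a subsample containing both classes")
        Xs = Xv[idx]
        mu = Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (Xs - mu) / sd
        model = XGBClassifier(**params, random_state=int(rng.integers(2**31 - 1)))
        model.fit(Xs, y[idx])
        importances[it] = _importance_vector(model, X.columns, importance_type)
    return pd.Series(np.median(importances, axis=0), index=X.columns)


def _ranked(imp: pd.Series, top_k: int) -> list:
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return order[:top_k]


def consensus_features(imp_forced: pd.Series, imp_tidal: pd.Series, top_k: int = 30,
                       n_iterations: int = 1000, subsample_fraction: float = 2 / 3,
                       seeds: list[int] | None = None) -> SelectionResult:
    """Intersect the per-maneuver top-``top_k`` ranked features.

    Rankings are by median importance, descending, with ties broken toward the
    lower m/z. An empty intersection is returned with a warning; the caller
    decides how to proceed.
    """
    if set(imp_forced.index) != set(imp_tidal.index):
        raise ConfigError("importance vectors must cover the same feature set")
    ranked = {"forced": _ranked(imp_forced, top_k), "tidal": _ranked(imp_tidal, top_k)}
    consensus = sorted(set(ranked["forced"]) & set(ranked["tidal"]))
    if not consensus:
        warnings.warn("consensus feature set is empty: per-maneuver top lists are disjoint")
    return SelectionResult(
        median_importance={"forced": imp_forced, "tidal": imp_tidal},
        ranked_lists=ranked, top_k=top_k, consensus_features=consensus,
        n_iterations=n_iterations, subsample_fraction=subsample_fraction,
        seeds=seeds or [])


def top_percent_features(imp: pd.Series, percent: float = 10.0) -> list:
    """Alternative selector: the top ``percent`` % of features by importance."""
    k = max(1, int(round(len(imp) * percent / 100.0)))
    return _ranked(imp, k)


def tune_and_fit(X: pd.DataFrame, y, cv_folds: int = 5, param_grid: dict | None = None,
                 seed: int | None = None) -> XGBClassifier:
    """Grid-search XGBoost hyperparameters by stratified K-fold AUC, then refit
    on the full training set."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise CVError("training labels contain a single class")
    if counts.min() < cv_folds:
        raise CVError(
            f"smallest class ({counts.min()}) cannot populate {cv_folds} stratified folds")
    grid = param_grid or DEFAULT_PARAM_GRID
    base = XGBClassifier(**{**DEFAULT_LEARNER_PARAMS, "random_state": seed or 0})
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, scoring="roc_auc", cv=cv, refit=True, n_jobs=1)
    search.fit(X.to_numpy(dtype=float), y)
    return search.best_estimator_


def _confusion_metrics(y: np.ndarray, prob: np.ndarray, threshold: float) -> dict:
    pred = prob >= threshold  # ties at the threshold count as positive
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    div = lambda a, b: a / b if b else float("nan")
    return {
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
    }


def evaluate(model, X: pd.DataFrame, y, threshold: float = 0.5,
             scheme: str = "holdout", endpoint: str = "diagnosis",
             n_train: int | None = None) -> ModelReport:
    """Model metrics at the probability threshold.

    ``holdout``: ``model`` is already fitted; ``X``/``y`` are the held-out set.
    ``loo``: ``model`` is (re)fitted on every leave-one-out training subset and
    the out-of-sample probabilities are aggregated before a single AUC /
    confusion computation.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUC is undefined for single-class labels")
    Xv = X.to_numpy(dtype=float)
    if scheme == "holdout":
        prob = model.predict_proba(Xv)[:, 1]
        n_tr = n_train if n_train is not None else 0
        n_te = len(y)
    elif scheme == "loo":
        prob = np.empty(len(y))
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            if len(np.unique(y[mask])) < 2:
                raise EvaluationError("leave-one-out training subset lost a class")
            m = clone(model)
            m.fit(Xv[mask], y[mask])
            prob[i] = m.predict_proba(Xv[i:i + 1])[0, 1]
        n_tr = len(y) - 1
        n_te = len(y)
    else:
        raise EvaluationError(f"unknown evaluation scheme {scheme!r}")
    metrics = _confusion_metrics(y, prob, threshold)
    return ModelReport(
        endpoint=endpoint, auc=float(roc_auc_score(y, prob)), threshold=threshold,
        cv_scheme=scheme, n_train=n_tr, n_test=n_te, **metrics)
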