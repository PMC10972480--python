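"""Classifier training and evaluation for the dyad / random-dyad problem.

Three model families run under one interface: random forest, LightGBM
gradient boosting, and elastic-net logistic regression (both L1 and L2
penalties). Models are scored with the Matthews correlation coefficient
(MCC) under stratified k-fold cross-validation; hyperparameters are tuned
by Bayesian optimization of the mean CV MCC, and the final model is judged
once on an untouched external test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import bayesopt
from .bayesopt import Dimension
from .dyads import DyadFeatureTable

ALGORITHMS = ("random_forest", "gradient_boosting", "elasticnet_logistic")

#: MCC level treated as clearly better than coin-tossing (fair agreement)
FAIR_AGREEMENT_MCC = 0.2


@dataclass
class ConfusionCounts:
    """Binary confusion counts at the 0.5 probability threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, with the
    convention that any zero factor in the denominator yields 0. Ranges
    over [-1, 1]; 0 is chance-level agreement.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return mcc(ConfusionCounts.from_predictions(y_true, y_pred))


@dataclass
class ModelSpec:
    """One classifier family plus its hyperparameters and search space."""

    algorithm: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; pick from {ALGORITHMS}")

    def search_space(self) -> list[Dimension]:
        return default_search_space(self.algorithm)

    def make_estimator(self, params: dict[str, Any] | None = None):
        merged = {**self.params, **(params or {})}
        return make_estimator(self.algorithm, merged, self.seed)


def default_search_space(algorithm: str) -> list[Dimension]:
    """Expert-default hyperparameter ranges per model family."""
    if algorithm == "random_forest":
        return [
            Dimension("n_estimators", 100, 250, "int"),
            Dimension("max_depth", 3, 14, "int"),
            Dimension("min_samples_leaf", 1, 10, "int"),
            Dimension("max_features", 0.02, 0.2, "float"),
        ]
    if algorithm == "gradient_boosting":
        return [
            Dimension("num_leaves", 7, 31, "int"),
            Dimension("learning_rate", 0.01, 0.3, "logfloat"),
            Dimension("n_estimators", 50, 200, "int"),
            Dimension("min_child_samples", 5, 50, "int"),
        ]
    if algorithm == "elasticnet_logistic":
        return [
            Dimension("C", 1e-3, 1e3, "logfloat"),
            Dimension("l1_ratio", 0.0, 1.0, "float"),
        ]
    raise ValueError(f"unknown algorithm {algorithm!r}")


def default_point(algorithm: str) -> dict[str, Any]:
    """A sensible in-space starting configuration, evaluated as trial 1."""
    if algorithm == "random_forest":
        return {"n_estimators": 200, "max_depth": 12,
                "min_samples_leaf": 1, "max_features": 0.1}
    if algorithm == "gradient_boosting":
        return {"num_leaves": 31, "learning_rate": 0.1,
                "n_estimators": 150, "min_child_samples": 20}
    if algorithm == "elasticnet_logistic":
        return {"C": 1.0, "l1_ratio": 0.5}
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_estimator(algorithm: str, params: dict[str, Any], seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 300)),
            max_depth=params.get("max_depth"),
            min_samples_leaf=int(params.get("min_samples_leaf", 1)),
            max_features=params.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "gradient_boosting":
        return LGBMClassifier(
            num_leaves=int(params.get("num_leaves", 31)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            n_estimators=int(params.get("n_estimators", 200)),
            min_child_samples=int(params.get("min_child_samples", 20)),
            random_state=seed,
            n_jobs=1,
            verbose=-1,
        )
    if algorithm == "elasticnet_logistic":
        return LogisticRegression(
            solver="saga",
            C=float(params.get("C", 1.0)),
            l1_ratio=float(params.get("l1_ratio", 0.5)),
            max_iter=int(params.get("max_iter", 5000)),
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def stratified_folds(y: np.ndarray, k: int, seed: int):
    """Stratified k-fold indices; rejects degenerate configurations."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= len(y):
        raise ValueError("leave-one-out folds are not supported (MCC undefined)")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("a label class is too small for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(
    spec: ModelSpec,
    train: DyadFeatureTable,
    k: int = 10,
    seed: int = 0,
    params: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Per-fold MCC of ``spec`` refit on each stratified training fold."""
    X, y = train.X, train.y
    folds = stratified_folds(y, k, seed)
    scores = []
    for tr_idx, va_idx in folds:
        model = spec.make_estimator(params)
        model.fit(X[tr_idx], y[tr_idx])
        pred = model.predict(X[va_idx])
        scores.append(mcc_from_labels(y[va_idx], pred))
    scores = np.asarray(scores)
    return {
        "fold_mcc": scores.tolist(),
        "mean_mcc": float(scores.mean()),
        "sd_mcc": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
    }


def tune(
    spec: ModelSpec,
    train: DyadFeatureTable,
    n_trials: int = 50,
    k: int = 10,
    seed: int = 0,
    space: list[Dimension] | None = None,
) -> tuple[dict[str, Any], list[bayesopt.Trial]]:
    """Bayesian optimization of mean CV MCC over the model's search space.

    The family's default configuration is evaluated as the first trial, so
    tuning can never end below the defaults on the same folds.
    """
    custom_space = space is not None
    space = space if custom_space else spec.search_space()

    def objective(params: dict[str, Any]) -> float:
        return cross_validate(spec, train, k=k, seed=seed, params=dict(params))["mean_mcc"]

    initial = None if custom_space else [default_point(spec.algorithm)]
    return bayesopt.maximize(objective, space, n_trials=n_trials, seed=seed,
                             initial=initial)


def fit_final(spec: ModelSpec, train: DyadFeatureTable, params: dict[str, Any] | None = None):
    """Fit the final model on the full training table."""
    model = spec.make_estimator(params)
    model.fit(train.X, train.y)
    return model


@dataclass
class EvaluationReport:
    """Test-set performance of one final model."""

    algorithm: str
    mcc_cv_mean: float
    mcc_cv_sd: float
    mcc_test: float
    accuracy_test: float
    auc_test: float
    confusion: ConfusionCounts
    n_features: int
    seed: int
    config: dict[str, Any] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.mcc_test <= 1.0 + 1e-9:
            raise ValueError("MCC out of [-1, 1]")
        if self.mcc_test > FAIR_AGREEMENT_MCC and not self.note:
            self.note = "above random (fair agreement)"

    def to_dict(self) -> dict[str, Any]:
        return {
            "algorithm": self.algorithm,
            "mcc_cv_mean": self.mcc_cv_mean,
            "mcc_cv_sd": self.mcc_cv_sd,
            "mcc_test": self.mcc_test,
            "accuracy_test": self.accuracy_test,
            "auc_test": self.auc_test,
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "n_features": self.n_features,
            "seed": self.seed,
            "config": self.config,
            "note": self.note,
        }


def evaluate(
    model,
    test: DyadFeatureTable,
    *,
    algorithm: str = "",
    cv_summary: dict[str, Any] | None = None,
    seed: int = 0,
    config: dict[str, Any] | None = None,
) -> EvaluationReport:
    """Score a trained model on the external test set.

    AUC is rank-based with ties averaged; the confusion matrix and MCC use
    the 0.5 probability threshold. A single-class test set has no defined
    AUC and is rejected.
    """
    y = test.y
    if len(np.unique(y)) < 2:
        raise ValueError("test set holds a single class; AUC undefined")
    proba = model.predict_proba(test.X)[:, 1]
    pred = (proba >= 0.5).astype(int)
    counts = ConfusionCounts.from_predictions(y, pred)
    cv_summary = cv_summary or {"mean_mcc": float("nan"), "sd_mcc": float("nan")}
    return EvaluationReport(
        algorithm=algorithm or type(model).__name__,
        mcc_cv_mean=cv_summary["mean_mcc"],
        mcc_cv_sd=cv_summary["sd_mcc"],
        mcc_test=mcc(counts),
        accuracy_test=float(accuracy_score(y, pred)),
        auc_test=float(roc_auc_score(y, proba)),
        confusion=counts,
        n_features=test.features.shape[1],
        seed=seed,
        config=config or {},
    )
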