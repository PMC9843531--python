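"""Classifier grid, evaluation metrics, ranking, and majority-vote ensemble.

Thirty models are trained: five algorithms (logistic regression, SVM, naive
Bayes, multilayer perceptron, random forest) crossed with six fingerprint
families. Hyperparameters come from an exhaustive grid scored by mean 5-fold
cross-validated MCC; models are ranked by validation MCC, and the top five
form a simple majority-vote ensemble.

Metric definitions used throughout (TP/TN/FP/FN from the confusion matrix):

    Q   = (TP + TN) / (TP + TN + FP + FN)
    SE  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention that a zero denominator yields 0 (a degenerate classifier
carries no correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, precision_recall_curve, roc_curve
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .chem import MODEL_FAMILIES

ALGORITHMS = ("logistic_regression", "svm", "naive_bayes", "mlp", "random_forest")

#: default hyperparameter grids, deliberately small and fully logged
DEFAULT_GRIDS: Dict[str, Dict[str, list]] = {
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
    "naive_bayes": {"alpha": [0.1, 1.0]},
    "mlp": {"hidden_layer_sizes": [(64,)], "alpha": [1e-4, 1e-3]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 10]},
}


class LeakageError(RuntimeError):
    """Raised when an evaluation set intersects the training ids."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(y_true: Sequence[int],
                               y_pred: Sequence[int]) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.n if cm.n else 0.0


def sensitivity(cm: ConfusionMatrix) -> float:
    den = cm.tp + cm.fn
    return cm.tp / den if den else 0.0


def specificity(cm: ConfusionMatrix) -> float:
    den = cm.tn + cm.fp
    return cm.tn / den if den else 0.0


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    den = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if den == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(den)


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    fingerprint: str
    grid: Tuple[Tuple[str, tuple], ...] = ()   # frozen form of the param grid
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def name(self) -> str:
        return f"{self.algorithm}_{self.fingerprint}"

    def param_grid(self) -> Dict[str, list]:
        if self.grid:
            return {k: list(v) for k, v in self.grid}
        return DEFAULT_GRIDS[self.algorithm]


def make_spec(algorithm: str, fingerprint: str, *, grid: Dict[str, list] | None = None,
              cv_folds: int = 5, seed: int = 0) -> ModelSpec:
    frozen = tuple((k, tuple(v)) for k, v in (grid or {}).items())
    return ModelSpec(algorithm=algorithm, fingerprint=fingerprint,
                     grid=frozen, cv_folds=cv_folds, seed=seed)


def _estimator(algorithm: str, params: Dict, seed: int, *, final: bool):
    """Fresh estimator for one grid point.

    SVMs only need calibrated probabilities for the final refit; during the
    cross-validation search predictions are hard labels, so Platt scaling is
    skipped there to keep the grid cheap.
    """
    if algorithm == "logistic_regression":
        return LogisticRegression(max_iter=5000, solver="liblinear",
                                  random_state=seed, **params)
    if algorithm == "svm":
        return SVC(probability=final, random_state=seed, **params)
    if algorithm == "naive_bayes":
        return BernoulliNB(**params)
    if algorithm == "mlp":
        return MLPClassifier(max_iter=300, random_state=seed, **params)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    best_params: Dict
    cv_mcc: float
    train_ids: FrozenSet[str]

    @property
    def name(self) -> str:
        return self.spec.name

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            positive = list(est.classes_).index(1)
            return proba[:, positive]
        scores = est.decision_function(X)  # pragma: no cover - all defaults have proba
        return 1.0 / (1.0 + np.exp(-scores))


def fit_with_gridsearch(spec: ModelSpec, X: np.ndarray, y: Sequence[int],
                        ids: Sequence[str]) -> TrainedModel:
    """Exhaustive grid search scored by mean CV MCC, then refit on all data.

    Ties between grid points keep the earlier point in grid order, so the
    selected hyperparameters are deterministic given (spec, data).
    """
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError(f"{spec.name}: training data contains a single class")
    if X.shape[0] != len(y) or len(ids) != len(y):
        raise ValueError("feature/label/id length mismatch")

    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(cv.split(X, y))

    best_params, best_score = None, -np.inf
    for params in ParameterGrid(spec.param_grid()):
        scores = []
        for train_idx, val_idx in folds:
            est = _estimator(spec.algorithm, params, spec.seed, final=False)
            est.fit(X[train_idx], y[train_idx])
            cm = confusion_from_predictions(y[val_idx], est.predict(X[val_idx]))
            scores.append(mcc(cm))
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = dict(params), score

    final = _estimator(spec.algorithm, best_params, spec.seed, final=True)
    final.fit(X, y)
    return TrainedModel(spec=spec, estimator=final, best_params=best_params,
                        cv_mcc=best_score, train_ids=frozenset(ids))


@dataclass
class EvalReport:
    model_name: str
    eval_set: str
    cm: ConfusionMatrix
    q: float
    se: float
    sp: float
    mcc: float
    roc_auc: float
    pr_auc: float
    predictions: np.ndarray = field(repr=False, default=None)
    scores: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> Dict:
        return {"model": self.model_name, "set": self.eval_set,
                "Q": self.q, "SE": self.se, "SP": self.sp,
                "AUC": self.roc_auc, "PR_AUC": self.pr_auc, "MCC": self.mcc,
                "TP": self.cm.tp, "FP": self.cm.fp,
                "TN": self.cm.tn, "FN": self.cm.fn}


def score_curves(scores: Sequence[float], labels: Sequence[int],
                 ) -> Tuple[float, float, pd.DataFrame, pd.DataFrame]:
    """ROC and precision-recall AUCs (trapezoid) plus curve point tables."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes required to compute ranking curves")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    roc_auc = float(auc(fpr, tpr))
    pr_auc = float(auc(recall, precision))
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr})
    pr_points = pd.DataFrame({"recall": recall, "precision": precision})
    return roc_auc, pr_auc, roc_points, pr_points


def evaluate(model: TrainedModel, X: np.ndarray, y: Sequence[int],
             ids: Sequence[str], eval_set: str = "validation",
             threshold: float = 0.5) -> EvalReport:
    """Score a trained model on a held-out set; hard-fails on id leakage."""
    overlap = model.train_ids & set(ids)
    if overlap:
        raise LeakageError(
            f"{model.name}: evaluation set {eval_set!r} shares "
            f"{len(overlap)} ids with the training set (e.g. {sorted(overlap)[:3]})")
    y = np.asarray(y, dtype=int)
    scores = model.predict_proba(X)
    preds = (scores >= threshold).astype(int)
    cm = confusion_from_predictions(y, preds)
    roc_auc, pr_auc, _, _ = score_curves(scores, y)
    return EvalReport(model_name=model.name, eval_set=eval_set, cm=cm,
                      q=accuracy(cm), se=sensitivity(cm), sp=specificity(cm),
                      mcc=mcc(cm), roc_auc=roc_auc, pr_auc=pr_auc,
                      predictions=preds, scores=scores)


def rank_models(reports: Sequence[EvalReport]) -> List[EvalReport]:
    """Descending MCC; ties broken by ROC AUC then model name."""
    sets = {r.eval_set for r in reports}
    if len(sets) > 1:
        raise ValueError(f"reports mix evaluation sets: {sorted(sets)}")
    return sorted(reports, key=lambda r: (-r.mcc, -r.roc_auc, r.model_name))


def top_k(reports: Sequence[EvalReport], k: int) -> List[EvalReport]:
    return rank_models(reports)[:k]


def ensemble_vote(predictions: np.ndarray) -> np.ndarray:
    """Majority vote over a (models x samples) 0/1 prediction matrix."""
    predictions = np.asarray(predictions, dtype=int)
    if predictions.ndim != 2:
        raise ValueError("expected a (models x samples) matrix")
    if predictions.shape[0] % 2 == 0:
        raise ValueError("majority voting requires an odd number of models")
    votes = predictions.sum(axis=0)
    return (votes > predictions.shape[0] / 2).astype(int)


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model (pickle) to ``<algorithm>_<fingerprint>.model``."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> TrainedModel:
    import pickle

    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model


def run_model_grid(features: Dict[str, Dict[str, np.ndarray]],
                   labels: Dict[str, np.ndarray],
                   ids: Dict[str, List[str]],
                   seed: int = 0,
                   algorithms: Sequence[str] = ALGORITHMS,
                   families: Sequence[str] = MODEL_FAMILIES,
                   grids: Dict[str, Dict[str, list]] | None = None,
                   ) -> Tuple[Dict[str, TrainedModel], List[EvalReport]]:
    """Train the full algorithm x fingerprint grid; evaluate on validation.

    ``features[family][split]`` is the 0/1 matrix for one fingerprint family
    and one of "train"/"validation"/"test".
    """
    models: Dict[str, TrainedModel] = {}
    reports: List[EvalReport] = []
    for family in families:
        for algorithm in algorithms:
            grid = (grids or {}).get(algorithm)
            spec = make_spec(algorithm, family, grid=grid, seed=seed)
            model = fit_with_gridsearch(spec, features[family]["train"],
                                        labels["train"], ids["train"])
            models[model.name] = model
            reports.append(evaluate(model, features[family]["validation"],
                                    labels["validation"], ids["validation"],
                                    eval_set="validation"))
    return models, reports
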