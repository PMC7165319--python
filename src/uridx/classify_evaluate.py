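"""Diagnostic classifiers and their evaluation.

Random forest, RBF support-vector machine and Gaussian naive Bayes
models are trained on a feature panel and evaluated three ways:
leave-one-out cross validation on the training cohort, prediction of an
independent validation cohort, and ROC analysis (including single-marker
models).  Acute appendicitis (AA) is the positive class throughout.

Default hyperparameters: RF with 500 trees and sqrt(k) features per
split; SVM with RBF kernel, C = 1 and gamma = 1/(k * Var(X)); Gaussian
naive Bayes — all overridable per call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .io_preprocess import AbundanceMatrix
from .panel_selection import FeaturePanel

logger = logging.getLogger(__name__)

POSITIVE = "AA"
NEGATIVE = "CON"
ALGORITHMS = ("rf", "svm", "nb")


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts with AA as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def as_percentages(self) -> dict[str, float]:
        """Rates as percentages rounded to one decimal (reporting precision)."""
        return {
            "accuracy": round(100 * self.accuracy, 1),
            "sensitivity": round(100 * self.sensitivity, 1),
            "specificity": round(100 * self.specificity, 1),
        }

    @classmethod
    def from_predictions(cls, y_true: Sequence[str], y_pred: Sequence[str]) -> "ClassificationMetrics":
        yt = np.asarray(y_true) == POSITIVE
        yp = np.asarray(y_pred) == POSITIVE
        return cls(
            tp=int((yt & yp).sum()),
            fp=int((~yt & yp).sum()),
            tn=int((~yt & ~yp).sum()),
            fn=int((yt & ~yp).sum()),
        )


@dataclass
class RocCurve:
    """ROC points with trapezoidal AUC and the Youden-optimal operating point."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float
    sensitivity_at_youden: float
    specificity_at_youden: float


@dataclass
class FittedModel:
    """A trained classifier bound to its panel, algorithm and seed."""

    estimator: object
    panel: tuple[str, ...]
    algo: str
    seed: int
    training_samples: tuple[str, ...]
    hyperparameters: dict


def make_estimator(algo: str, seed: int, n_features: int,
                   hyperparameters: dict | None = None):
    """Instantiate a classifier with the package defaults for ``algo``."""
    params = dict(hyperparameters or {})
    if algo == "rf":
        base = dict(n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1)
        base.update(params)
        return RandomForestClassifier(**base), base
    if algo == "svm":
        base = dict(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
        base.update(params)
        return SVC(**base), base
    if algo == "nb":
        return GaussianNB(**params), params
    raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")


def _panel_ids(panel) -> list[str]:
    if isinstance(panel, FeaturePanel):
        return list(panel.protein_ids)
    return list(panel)


def _design(matrix: AbundanceMatrix, metadata: pd.DataFrame, panel_ids: list[str]):
    """Samples x panel design, rows in sorted-sample-id order (for
    order-invariant fits)."""
    missing = [p for p in panel_ids if p not in matrix.data.index]
    if missing:
        raise KeyError(f"panel proteins absent from matrix: {missing}")
    meta = metadata[metadata["sample_id"].isin(matrix.data.columns)]
    ids = sorted(meta["sample_id"])
    X = matrix.data.loc[panel_ids, ids].T.to_numpy()
    y = meta.set_index("sample_id").loc[ids, "group"].to_numpy()
    return X, y, ids


def train_classifier(matrix: AbundanceMatrix, metadata: pd.DataFrame, panel,
                     algo: str = "rf", seed: int = 0,
                     hyperparameters: dict | None = None) -> FittedModel:
    """Fit one classifier on a log2-imputed matrix restricted to the panel."""
    ids = _panel_ids(panel)
    X, y, samples = _design(matrix, metadata, ids)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    est, params = make_estimator(algo, seed, len(ids), hyperparameters)
    est.fit(X, y)
    return FittedModel(est, tuple(ids), algo, seed, tuple(samples), params)


def predict(model: FittedModel, matrix: AbundanceMatrix, metadata: pd.DataFrame) -> pd.Series:
    """Class predictions for every sample present in matrix and metadata."""
    X, _, samples = _design(matrix, metadata, list(model.panel))
    return pd.Series(model.estimator.predict(X), index=samples, name="prediction")


def decision_scores(model: FittedModel, matrix: AbundanceMatrix,
                    metadata: pd.DataFrame) -> pd.Series:
    """Continuous AA-vs-CON scores (probability of AA, or SVM margin)."""
    X, _, samples = _design(matrix, metadata, list(model.panel))
    est = model.estimator
    if hasattr(est, "predict_proba"):
        pos = list(est.classes_).index(POSITIVE)
        scores = est.predict_proba(X)[:, pos]
    else:
        scores = est.decision_function(X)
        if list(est.classes_)[1] != POSITIVE:  # decision_function favors classes_[1]
            scores = -scores
    return pd.Series(scores, index=samples, name="score")


def loocv(matrix: AbundanceMatrix, metadata: pd.DataFrame, panel=None,
          algo: str | Callable[[], object] = "rf", seed: int = 0,
          hyperparameters: dict | None = None,
          panel_fn: Callable[[AbundanceMatrix, pd.DataFrame], Sequence[str]] | None = None,
          ) -> tuple[ClassificationMetrics, pd.Series]:
    """Leave-one-out cross validation.

    Each of the n samples is predicted exactly once by a model trained on
    the other n-1.  ``algo`` may also be a zero-argument factory
    returning a scikit-learn style estimator (used for stub classifiers
    in testing).  When ``panel_fn`` is given, the feature panel is
    re-derived inside every fold from the training samples only (honest
    cross validation, avoiding selection leakage); otherwise the fixed
    ``panel`` is used for all folds.
    """
    if panel is None and panel_fn is None:
        raise ValueError("either a fixed panel or a panel_fn is required")
    meta = metadata[metadata["sample_id"].isin(matrix.data.columns)]
    all_ids = sorted(meta["sample_id"])
    if len(all_ids) < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    labels = meta.set_index("sample_id").loc[all_ids, "group"]
    preds = {}
    for held in all_ids:
        train_ids = [s for s in all_ids if s != held]
        train_meta = meta[meta["sample_id"].isin(train_ids)]
        if panel_fn is not None:
            fold_panel = _panel_ids(panel_fn(matrix.select_samples(train_ids), train_meta))
        else:
            fold_panel = _panel_ids(panel)
        ytr = labels.loc[train_ids]
        if ytr.nunique() < 2:
            warnings.warn(f"fold holding out {held!r} has single-class training data; "
                          "predicting the majority class", UserWarning, stacklevel=2)
            preds[held] = ytr.mode().iloc[0]
            continue
        Xtr = matrix.data.loc[fold_panel, train_ids].T.to_numpy()
        if callable(algo):
            est = algo()
        else:
            est, _ = make_estimator(algo, seed, len(fold_panel), hyperparameters)
        est.fit(Xtr, ytr.to_numpy())
        xh = matrix.data.loc[fold_panel, [held]].T.to_numpy()
        preds[held] = est.predict(xh)[0]
    pred_series = pd.Series(preds).loc[all_ids]
    metrics = ClassificationMetrics.from_predictions(labels.to_numpy(), pred_series.to_numpy())
    return metrics, pred_series


def evaluate(model: FittedModel, validation_matrix: AbundanceMatrix,
             validation_metadata: pd.DataFrame) -> ClassificationMetrics:
    """Confusion metrics of a trained model on an independent cohort.

    Validation samples must be disjoint from the training samples.
    """
    v_ids = set(validation_metadata["sample_id"]) & set(validation_matrix.sample_ids)
    overlap = v_ids & set(model.training_samples)
    if overlap:
        raise ValueError(f"validation samples overlap training set: {sorted(overlap)[:5]}")
    pred = predict(model, validation_matrix, validation_metadata)
    truth = validation_metadata.set_index("sample_id").loc[pred.index, "group"]
    return ClassificationMetrics.from_predictions(truth.to_numpy(), pred.to_numpy())


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC for continuous scores against AA/CON labels.

    AUC equals the probability that a random AA sample scores above a
    random CON sample, ties counted half — the trapezoidal area under
    the full (no intermediate points dropped) ROC curve.  The reported
    operating point maximizes Youden's J = sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    y_bin = (y == POSITIVE).astype(int)
    fpr, tpr, thr = roc_curve(y_bin, scores, drop_intermediate=False)
    auc = float(roc_auc_score(y_bin, scores))
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocCurve(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        youden_threshold=float(thr[best]),
        sensitivity_at_youden=float(tpr[best]),
        specificity_at_youden=float(1 - fpr[best]),
    )


def confusion_from_rates(n_pos: int, n_neg: int, sensitivity_pct: float,
                         specificity_pct: float, decimals: int = 1) -> ClassificationMetrics:
    """Recover the integer confusion table implied by printed rates.

    Searches all (tp, tn) on ``n_pos`` positives and ``n_neg`` negatives
    for counts whose sensitivity and specificity reproduce the printed
    percentages at the given decimal precision (within half a printed
    unit).  Errors unless exactly one table matches — the printed rates
    then determine the accuracy unambiguously.
    """
    half_unit = 0.5 * 10.0 ** (-decimals) + 1e-9
    matches = []
    for tp in range(n_pos + 1):
        if abs(100.0 * tp / n_pos - sensitivity_pct) > half_unit:
            continue
        for tn in range(n_neg + 1):
            if abs(100.0 * tn / n_neg - specificity_pct) <= half_unit:
                matches.append(ClassificationMetrics(tp=tp, fp=n_neg - tn,
                                                     tn=tn, fn=n_pos - tp))
    if len(matches) != 1:
        raise ValueError(
            f"{len(matches)} confusion tables consistent with sens={sensitivity_pct}%, "
            f"spec={specificity_pct}% on {n_pos}/{n_neg}"
        )
    return matches[0]
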