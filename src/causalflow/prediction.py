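"""Multivariate evaluation of flow features: SVC under leave-one-out
cross-validation and lasso prediction of continuous outcomes.

Feature selection mirrors the study protocol: edges/nodes that survive the
group-difference FDR threshold on the *full* sample feed the classifier.
That reuses the test set for selection and optimistically biases LOOCV
accuracy; a nested-selection mode (selection redone inside every training
fold) is provided and recommended for unbiased estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import LeaveOneOut
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .inference import StatReport, bh_fdr

__all__ = [
    "ClassificationReport",
    "PredictionReport",
    "FeatureSelectionError",
    "select_significant_features",
    "confusion_metrics",
    "loocv_svc",
    "nested_loocv_svc",
    "lasso_predict",
    "pearson_r",
]


class FeatureSelectionError(ValueError):
    """No feature survived the significance filter."""


@dataclass
class ClassificationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_label: str
    metrics: dict
    fold_predictions: pd.DataFrame = None
    feature_names: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class PredictionReport:
    outcome: str
    r: float
    p: float
    n_selected: int
    coefficients: np.ndarray
    predicted: np.ndarray
    actual: np.ndarray
    mode: str
    alpha: float = None
    feature_names: list = field(default_factory=list)


def select_significant_features(report: StatReport, features: np.ndarray,
                                names: list):
    """Keep the columns whose FDR-significant flag is set, in report order.

    ``features`` is subjects x features aligned with ``names`` and with the
    report's id column.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[1] != len(names):
        raise ValueError("feature matrix width does not match names")
    sig_ids = report.significant_ids()
    if not sig_ids:
        raise FeatureSelectionError(
            "no unit survives the FDR threshold; lower the level, use a "
            "larger cohort, or switch to nested selection with a pre-filter"
        )
    name_to_col = {n: k for k, n in enumerate(names)}
    missing = [s for s in sig_ids if s not in name_to_col]
    if missing:
        raise ValueError(f"report ids not present in feature names: {missing[:5]}")
    cols = [name_to_col[s] for s in sig_ids]
    return features[:, cols], sig_ids


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV as percentages rounded
    to 2 decimals; ratios with a zero denominator are reported as None."""
    counts = (tp, fn, tn, fp)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("counts must be non-negative integers")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty confusion matrix")

    def pct(num, den):
        return round(100.0 * num / den, 2) if den > 0 else None

    return {
        "accuracy": pct(tp + tn, total),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def loocv_svc(features: np.ndarray, labels, positive_label="HC",
              kernel: str = "linear", C: float = 1.0,
              feature_names=None) -> ClassificationReport:
    """Leave-one-out cross-validated support-vector classification.

    Feature standardization is fit on each training fold only.  The
    confusion matrix is aggregated over the n held-out predictions.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be subjects x features aligned with labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < 2:
        raise ValueError(
            "each class needs >= 2 subjects (a training fold would contain one class only)"
        )
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among classes {list(classes)}")

    preds = np.empty(y.size, dtype=object)
    for train, test in LeaveOneOut().split(X):
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel=kernel, C=C).fit(scaler.transform(X[train]), y[train])
        preds[test[0]] = clf.predict(scaler.transform(X[test]))[0]

    pos = y == positive_label
    pred_pos = preds == positive_label
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    folds = pd.DataFrame({"true": y, "predicted": preds.astype(str)})
    return ClassificationReport(
        tp=tp, fn=fn, tn=tn, fp=fp, positive_label=str(positive_label),
        metrics=confusion_metrics(tp, fn, tn, fp),
        fold_predictions=folds,
        feature_names=list(feature_names) if feature_names is not None else [],
    )


def nested_loocv_svc(features: np.ndarray, labels, level: float = 0.05,
                     variant: str = "student", positive_label="HC",
                     kernel: str = "linear", C: float = 1.0) -> ClassificationReport:
    """LOOCV-SVC with feature selection redone inside every training fold.

    Unlike the pooled protocol, the held-out subject never informs which
    features are used, so the accuracy estimate is leakage-free.  Folds in
    which no feature survives the FDR threshold fall back to the single
    smallest-p feature so every subject still receives a prediction.
    """
    from .inference import _feature_ttests

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 3:
        raise ValueError("two classes with >= 3 subjects each required")
    preds = np.empty(y.size, dtype=object)
    for train, test in LeaveOneOut().split(X):
        ga = X[train][y[train] == classes[0]]
        gb = X[train][y[train] == classes[1]]
        _, p = _feature_ttests(ga, gb, variant)
        _, reject = bh_fdr(p, level)
        cols = np.flatnonzero(reject)
        if cols.size == 0:
            cols = np.array([int(np.argmin(p))])
        scaler = StandardScaler().fit(X[train][:, cols])
        clf = SVC(kernel=kernel, C=C).fit(
            scaler.transform(X[train][:, cols]), y[train])
        preds[test[0]] = clf.predict(scaler.transform(X[test][:, cols]))[0]
    pos = y == positive_label
    pred_pos = preds == positive_label
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    folds = pd.DataFrame({"true": y, "predicted": preds.astype(str)})
    return ClassificationReport(
        tp=tp, fn=fn, tn=tn, fp=fp, positive_label=str(positive_label),
        metrics=confusion_metrics(tp, fn, tn, fp), fold_predictions=folds)


def lasso_predict(features: np.ndarray, outcome, mode: str = "in_sample",
                  outcome_name: str = "outcome", alpha: float = None,
                  cv: int = 5, seed: int = 0,
                  feature_names=None) -> PredictionReport:
    """L1-penalized prediction of a continuous outcome from flow features.

    The penalty is chosen by internal cross-validation on a log-spaced grid
    unless ``alpha`` is given.  ``in_sample`` scores predictions of the full
    fit (single-fit protocol); ``loocv`` refits on every leave-one-out
    training fold and scores the held-out predictions.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float).ravel()
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[mask], y[mask]
    if y.size < 10:
        raise ValueError("need >= 10 complete-case subjects")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    if mode not in ("in_sample", "loocv"):
        raise ValueError(f"unknown mode {mode!r}")

    def fit_one(Xtr, ytr):
        scaler = StandardScaler().fit(Xtr)
        Z = scaler.transform(Xtr)
        if alpha is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = LassoCV(cv=cv, alphas=100, eps=1e-4,
                                random_state=seed, max_iter=5000).fit(Z, ytr)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = Lasso(alpha=alpha, max_iter=5000).fit(Z, ytr)
        return scaler, model

    scaler, model = fit_one(X, y)
    coef = model.coef_.copy()
    n_selected = int(np.sum(coef != 0))
    chosen_alpha = float(getattr(model, "alpha_", getattr(model, "alpha", np.nan)))

    if mode == "in_sample":
        predicted = model.predict(scaler.transform(X))
    else:
        predicted = np.empty_like(y)
        for train, test in LeaveOneOut().split(X):
            sc, mo = fit_one(X[train], y[train])
            predicted[test[0]] = mo.predict(sc.transform(X[test]))[0]

    if np.ptp(predicted) == 0:
        warnings.warn("all lasso coefficients shrunk to zero; r reported as 0")
        r, p = 0.0, 1.0
    else:
        r, p = pearson_r(predicted, y)
    return PredictionReport(
        outcome=outcome_name, r=r, p=p, n_selected=n_selected,
        coefficients=coef, predicted=predicted, actual=y, mode=mode,
        alpha=chosen_alpha,
        feature_names=list(feature_names) if feature_names is not None else [],
    )


def pearson_r(x, y):
    """Product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
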