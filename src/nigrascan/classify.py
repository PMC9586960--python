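"""Feature standardization, PCA reduction, and cross-validated classification.

Features are z-scored (``(x - mean) / SD``, population SD), optionally
reduced by PCA to the smallest number of components whose cumulative
explained variance reaches a target fraction (0.85 for the MRI feature
path), and fed to a suite of standard classifiers evaluated by stratified
k-fold cross-validation.  Metrics (ROC-AUC, per-class precision and recall,
overall accuracy) are computed from the pooled out-of-fold predictions; the
best model by accuracy is refit on all data for out-of-sample use, e.g.
scoring at-risk subjects who later phenoconvert.

By default the standardization and PCA transforms are fitted inside each
training fold only, so no information leaks from the held-out fold;
``paper_mode=True`` instead fits them once on the full dataset before
cross-validating the classifier, mirroring the common GUI-tool workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, precision_score, recall_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["standardize", "pca_reduce", "train_eval_cv", "predict_subject",
           "default_algorithms", "EvalReport", "FittedModel",
           "PCA_VARIANCE_TARGET"]

PCA_VARIANCE_TARGET = 0.85


def default_algorithms(seed: int = 0) -> dict:
    """The evaluated classifier suite: trees, discriminant analysis, SVM,
    logistic regression, nearest neighbours, naive Bayes, and an ensemble."""
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
        "svm": SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        "logistic": LogisticRegression(max_iter=2000),
        "knn": KNeighborsClassifier(),
        "naive_bayes": GaussianNB(),
        "ensemble": RandomForestClassifier(n_estimators=100, random_state=seed),
    }


def standardize(table: pd.DataFrame):
    """Z-score each column with population (1/n) SD.

    Zero-variance columns are dropped with a warning.  Returns
    ``(standardized, means, sds)``; the means/SDs allow out-of-sample
    application of the same transform.
    """
    table = table.astype(float)
    sds = table.std(ddof=0)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all features are constant; nothing to standardize")
    if not keep.all():
        dropped = list(sds.index[~keep])
        warnings.warn(f"dropping zero-variance features: {dropped}")
    table = table.loc[:, keep]
    means = table.mean()
    sds = sds[keep]
    return (table - means) / sds, means, sds


def pca_reduce(table: pd.DataFrame | np.ndarray,
               variance_target: float = PCA_VARIANCE_TARGET):
    """PCA retaining the minimal component count reaching the variance target.

    Expects standardized input.  Returns ``(scores, pca)`` where ``pca`` is
    the fitted :class:`sklearn.decomposition.PCA` (loadings in
    ``pca.components_``, ``pca.n_components_`` components retained).
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    X = np.asarray(table, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least two subjects")
    n_components = None if variance_target == 1 else variance_target
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca


def _make_pipeline(clf, variance_target):
    steps = [("scale", StandardScaler())]
    if variance_target is not None:
        steps.append(("pca", PCA(n_components=variance_target, svd_solver="full")))
    steps.append(("clf", clone(clf)))
    return Pipeline(steps)


def _decision_scores(model, X, classes):
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    proba = model.predict_proba(X)
    return proba[:, list(model.classes_).index(classes[1])]


@dataclass(frozen=True)
class FittedModel:
    """A refit pipeline plus the training feature schema."""

    algorithm: str
    pipeline: Pipeline
    feature_names: tuple
    classes: tuple


@dataclass(frozen=True)
class EvalReport:
    """Cross-validation metrics for every evaluated algorithm."""

    metrics: dict  # algorithm -> {auc, accuracy, precision: {cls}, recall: {cls}}
    fold_assignments: np.ndarray
    seed: int
    n_folds: int
    best_algorithm: str
    best_model: FittedModel
    n_components_retained: int | None = None


def train_eval_cv(features: pd.DataFrame, labels, algorithms: dict | None = None,
                  n_folds: int = 5, seed: int = 0,
                  variance_target: float | None = None,
                  paper_mode: bool = False) -> EvalReport:
    """Evaluate a classifier suite with stratified k-fold cross-validation.

    Parameters
    ----------
    features : DataFrame
        Subjects x numeric features.
    labels : array-like
        Class label per subject (two classes).
    algorithms : dict, optional
        Name -> unfitted sklearn estimator; defaults to
        :func:`default_algorithms`.
    variance_target : float, optional
        If given, insert a PCA step retaining this explained-variance
        fraction (the MRI feature path uses 0.85); ``None`` disables PCA
        (the SBR path).
    paper_mode : bool
        Fit standardization/PCA on the full dataset before cross-validating
        instead of inside each training fold.

    Returns
    -------
    EvalReport
        Pooled out-of-fold AUC, accuracy, and per-class precision/recall per
        algorithm; the best model (by accuracy) refit on all data.
    """
    if algorithms is None:
        algorithms = default_algorithms(seed)
    X = features.astype(float)
    y = np.asarray(labels)
    classes = tuple(np.unique(y))
    if len(classes) < 2:
        raise ValueError("classification requires at least two classes")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds subjects")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    fold_assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = fold

    if paper_mode:
        Xg, _, _ = standardize(X)
        if variance_target is not None:
            Xg, _ = pca_reduce(Xg, variance_target)
        X_cv = np.asarray(Xg, dtype=float)
        pipe_variance = None
    else:
        X_cv = X.to_numpy(dtype=float)
        pipe_variance = variance_target

    metrics = {}
    for name, clf in algorithms.items():
        pred = np.empty(len(y), dtype=object)
        score = np.empty(len(y), dtype=float)
        for train_idx, test_idx in splits:
            pipe = _make_pipeline(clf, pipe_variance)
            pipe.fit(X_cv[train_idx], y[train_idx])
            pred[test_idx] = pipe.predict(X_cv[test_idx])
            score[test_idx] = _decision_scores(pipe, X_cv[test_idx], classes)
        pred = pred.astype(y.dtype)
        auc = float(roc_auc_score((y == classes[1]).astype(int), score))
        metrics[name] = {
            "accuracy": float(accuracy_score(y, pred)),
            "auc": auc,
            "precision": dict(zip(classes, precision_score(
                y, pred, labels=list(classes), average=None, zero_division=0))),
            "recall": dict(zip(classes, recall_score(
                y, pred, labels=list(classes), average=None, zero_division=0))),
        }

    best = max(metrics, key=lambda name: metrics[name]["accuracy"])
    best_pipe = _make_pipeline(algorithms[best], variance_target)
    best_pipe.fit(X.to_numpy(dtype=float), y)
    n_comp = None
    if variance_target is not None:
        n_comp = int(best_pipe.named_steps["pca"].n_components_)
    model = FittedModel(algorithm=best, pipeline=best_pipe,
                        feature_names=tuple(X.columns), classes=classes)
    return EvalReport(metrics=metrics, fold_assignments=fold_assignments,
                      seed=seed, n_folds=n_folds, best_algorithm=best,
                      best_model=model, n_components_retained=n_comp)


def predict_subject(model: FittedModel, features) -> tuple:
    """Classify one subject with a refit model.

    ``features`` is a mapping or Series of feature name -> value; its keys
    must match the training schema exactly.  Returns ``(label, score)``
    where the score is the decision value toward the second class.
    """
    feats = dict(features)
    missing = [n for n in model.feature_names if n not in feats]
    extra = [n for n in feats if n not in model.feature_names]
    if missing or extra:
        raise ValueError(f"feature schema mismatch; missing={missing}, extra={extra}")
    x = np.asarray([[float(feats[n]) for n in model.feature_names]])
    label = model.pipeline.predict(x)[0]
    score = float(_decision_scores(model.pipeline, x, model.classes)[0])
    return label, score
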