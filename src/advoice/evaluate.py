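"""Single-explanatory-variable classifier evaluation with fivefold CV.

Each screened feature is evaluated on its own as the sole input of three
classifiers — L2-regularized logistic regression (LR), an RBF-kernel soft
margin SVM, and a 100-tree random forest (RF) — under stratified fivefold
cross-validation (80% train / 20% test per fold), with no hyperparameter
search. Reported per feature and classifier: fold-wise accuracy, F1 (positive
class = patient), and AUC, summarized as mean +- population SD over the five
folds, plus the per-fold ROC points.

The feature is standardized inside each fold using training-fold statistics
only. Fold assignment defaults to pooled block rows; with
``group_by_subject=True`` all blocks of one subject share a fold, preventing
subject leakage between train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

CLASSIFIERS = ("LR", "SVM", "RF")
POSITIVE = "patient"


class FoldError(ValueError):
    """A cross-validation fold cannot be trained (e.g. single-class)."""


@dataclass
class FoldPlan:
    """Stratified k-fold partition of the feature-table rows."""

    k: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx) pairs
    group_by_subject: bool = False


@dataclass
class EvalResult:
    """Fold-wise metrics of one (feature, classifier) pair."""

    feature: str
    classifier: str
    accuracy: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    auc: list[float] = field(default_factory=list)
    roc: list[dict] = field(default_factory=list)  # per fold: fpr/tpr/thresholds

    def mean_sd(self, metric: str) -> tuple[float, float]:
        v = np.asarray(getattr(self, metric), dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return np.nan, np.nan
        return float(v.mean()), float(v.std())  # population SD over folds


def make_folds(table: pd.DataFrame, k: int = 5, seed: int = 0,
               group_by_subject: bool = False) -> FoldPlan:
    """Stratified k-fold plan over the table's rows.

    With ``group_by_subject`` every block of a subject lands in the same
    fold (stratification then operates at subject granularity).
    """
    y = (table["group"] == POSITIVE).to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise FoldError(f"each class needs >= {k} rows; got {counts.tolist()}")
    idx = np.arange(len(table))
    if group_by_subject:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, y, groups=table["subject_id"].to_numpy())
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, y)
    folds = [(tr.copy(), te.copy()) for tr, te in splits]
    return FoldPlan(k=k, seed=seed, folds=folds, group_by_subject=group_by_subject)


def _make_model(classifier: str, seed: int):
    if classifier == "LR":
        return LogisticRegression()
    if classifier == "SVM":
        return SVC(kernel="rbf")
    if classifier == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier {classifier!r}; expected one of {CLASSIFIERS}")


def fit_score(x_train, y_train, x_test, classifier: str, seed: int = 0):
    """Train one classifier on a single feature and score the test rows.

    The feature is standardized with training-fold mean/SD. Scores are the
    probability of the patient class (LR, RF) or the signed decision value
    (SVM); hard predictions use the corresponding natural threshold.
    """
    x_train = np.asarray(x_train, dtype=float).reshape(-1, 1)
    x_test = np.asarray(x_test, dtype=float).reshape(-1, 1)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise FoldError("training fold contains a single class")
    mu = x_train.mean()
    sigma = x_train.std()
    if sigma == 0:
        sigma = 1.0
    z_train = (x_train - mu) / sigma
    z_test = (x_test - mu) / sigma
    model = _make_model(classifier, seed)
    model.fit(z_train, y_train)
    if classifier == "SVM":
        scores = model.decision_function(z_test)
        preds = (scores >= 0).astype(int)
    else:
        scores = model.predict_proba(z_test)[:, 1]
        preds = (scores >= 0.5).astype(int)
    return scores, preds


def metrics(scores, predictions, labels):
    """(accuracy, F1, AUC, ROC points) of one test fold.

    F1 uses patient as the positive class and is 0 when there are no positive
    predictions; AUC is the Mann-Whitney statistic of the scores (ties count
    one-half) and is missing when the fold holds a single class. ROC points
    come from a full threshold sweep (no point dropping), so the trapezoidal
    area under them equals the AUC.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    scores = np.asarray(scores, dtype=float)
    acc = float(accuracy_score(labels, predictions))
    f1 = float(f1_score(labels, predictions, zero_division=0))
    if len(np.unique(labels)) < 2:
        log.warning("single-class test fold: AUC missing")
        return acc, f1, np.nan, None
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    roc = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "thresholds": thr.tolist()}
    return acc, f1, auc, roc


def evaluate_feature(table: pd.DataFrame, feature: str,
                     classifiers=CLASSIFIERS, foldplan: FoldPlan | None = None,
                     seed: int = 0) -> list[EvalResult]:
    """Fold-wise evaluation of one feature under each classifier.

    Rows with a missing value of the feature are dropped from each fold
    (logged). Raises :class:`FoldError` if any training fold then holds a
    single class.
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    plan = foldplan or make_folds(table, seed=seed)
    x = table[feature].to_numpy(dtype=float)
    y = (table["group"] == POSITIVE).to_numpy(dtype=int)
    ok = np.isfinite(x)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("%s: dropping %d rows with missing values", feature, n_drop)

    results = [EvalResult(feature=feature, classifier=c) for c in classifiers]
    for fold_no, (tr, te) in enumerate(plan.folds):
        tr = tr[ok[tr]]
        te = te[ok[te]]
        if len(np.unique(y[tr])) < 2:
            raise FoldError(f"{feature}: fold {fold_no} training data is single-class")
        for res in results:
            scores, preds = fit_score(x[tr], y[tr], x[te], res.classifier,
                                      seed=plan.seed)
            acc, f1, auc, roc = metrics(scores, preds, y[te])
            res.accuracy.append(acc)
            res.f1.append(f1)
            res.auc.append(auc)
            res.roc.append(roc)
    return results


def evaluate_all(table: pd.DataFrame, comparison: pd.DataFrame,
                 classifiers=CLASSIFIERS, seed: int = 0, k: int = 5,
                 group_by_subject: bool = False) -> list[EvalResult]:
    """Evaluate every significant feature of the screening, in canonical order."""
    sig = [f for f in FEATURE_NAMES
           if f in set(comparison.loc[comparison["significant"], "feature"])]
    if not sig:
        log.warning("no significant features to evaluate")
        return []
    plan = make_folds(table, k=k, seed=seed, group_by_subject=group_by_subject)
    out: list[EvalResult] = []
    for feat in sig:
        out.extend(evaluate_feature(table, feat, classifiers, plan, seed=seed))
    return out


def results_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Long-format fold metrics: feature, classifier, fold, accuracy, f1, auc."""
    rows = []
    for r in results:
        for i in range(len(r.accuracy)):
            rows.append({"feature": r.feature, "classifier": r.classifier,
                         "fold": i, "accuracy": r.accuracy[i],
                         "f1": r.f1[i], "auc": r.auc[i]})
    return pd.DataFrame(rows)


def summary_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Mean +- SD per feature x classifier x metric (the performance tables)."""
    rows = []
    for r in results:
        row = {"feature": r.feature, "classifier": r.classifier}
        for metric in ("accuracy", "f1", "auc"):
            m, s = r.mean_sd(metric)
            row[f"{metric}_mean"] = m
            row[f"{metric}_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def roc_payload(results: list[EvalResult]) -> dict:
    """JSON-serializable per-fold ROC curves keyed by feature then classifier."""
    out: dict = {}
    for r in results:
        out.setdefault(r.feature, {})[r.classifier] = [
            roc if roc is not None else None for roc in r.roc
        ]
    return out
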