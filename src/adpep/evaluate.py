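"""Cross-validation, confusion matrices, and the metric suite.

The evaluation stage runs stratified 10-fold cross-validation with the
whole preprocessing chain — standardization and lasso feature selection —
refit inside each training fold, so no information from a test fold ever
reaches the model that scores it.  Out-of-fold predictions are pooled into
one confusion matrix per method; per-fold AUC and accuracy are kept for
fold-stability summaries.

Metric conventions (with the positive class recorded explicitly):

====================  =====================================================
ACC                   (TP + TN) / (TP + TN + FP + FN)
Precision (PPV)       TP / (TP + FP);  0 when the denominator is 0
Sensitivity (recall)  TP / (TP + FN);  0 when the denominator is 0
Specificity           TN / (FP + TN);  0 when the denominator is 0
F1                    harmonic mean of precision and sensitivity
MCC                   (TP*TN - FP*FN) / sqrt(prod of marginals); 0 when any
                      marginal is 0
AUC                   trapezoid over the threshold-sweep ROC; equals the
                      normalized Mann-Whitney U with ties counted 1/2
====================  =====================================================

Because published tables sometimes follow a different orientation of the
2x2 matrix, :func:`orientation_report` computes the full rate set under
both choices of positive label side by side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import classify as _classify
from . import select as _select


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: int = 1

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions viewed with the other positive label."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp,
                               tn=self.tp,
                               positive_label=1 - self.positive_label)


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    auc: float | None = None
    positive_label: int = 1

    def rounded(self, digits: int = 3) -> dict[str, float | None]:
        out = {}
        for name in ("acc", "auc", "sensitivity", "specificity",
                     "precision", "f1", "mcc"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, digits)
        return out


def confusion(labels, predictions, positive_label: int = 1) -> ConfusionMatrix:
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    if set(np.unique(labels)) - {0, 1} or set(np.unique(predictions)) - {0, 1}:
        raise ValueError("labels and predictions must be over {0, 1}")
    pos = positive_label
    return ConfusionMatrix(
        tp=int(np.sum((labels == pos) & (predictions == pos))),
        fp=int(np.sum((labels != pos) & (predictions == pos))),
        fn=int(np.sum((labels == pos) & (predictions != pos))),
        tn=int(np.sum((labels != pos) & (predictions != pos))),
        positive_label=pos)


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricSet:
    """Eq.-style confusion-matrix metrics with explicit zero conventions."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / total
    pre = tp / (tp + fp) if tp + fp else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (fp + tn) if fp + tn else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricSet(acc=acc, sensitivity=sen, specificity=sp, precision=pre,
                     f1=f1, mcc=mcc, auc=auc,
                     positive_label=cm.positive_label)


def extended_rates(cm: ConfusionMatrix) -> dict[str, float]:
    """PPV, NPV, sensitivity and specificity of one orientation."""
    m = metrics(cm)
    npv = cm.tn / (cm.tn + cm.fn) if cm.tn + cm.fn else 0.0
    return {"ppv": m.precision, "npv": npv,
            "sensitivity": m.sensitivity, "specificity": m.specificity}


def orientation_report(cm: ConfusionMatrix) -> dict:
    """Metric suite under both positive-label conventions, side by side.

    ACC and MCC are orientation-invariant; precision/sensitivity/
    specificity/F1 are not, so published values can only be matched once
    the orientation (and occasionally a PPV/NPV relabelling) is known.
    """
    other = cm.swapped()
    return {
        f"positive_label_{cm.positive_label}": {
            **metrics(cm).rounded(), **{k: round(v, 3) for k, v in
                                        extended_rates(cm).items()}},
        f"positive_label_{other.positive_label}": {
            **metrics(other).rounded(), **{k: round(v, 3) for k, v in
                                           extended_rates(other).items()}},
    }


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(labels, scores, positive_label: int = 1) -> RocCurve:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid.

    The trapezoid over tied-score groups makes the AUC identical to the
    normalized Mann-Whitney U statistic with ties counted one half.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order].astype(float)
    sorted_scores = scores[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0],
                     len(sorted_scores) - 1]
    tps = np.cumsum(sorted_pos)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    method: str
    fold_assignments: pd.Series          # id -> fold index 1..k
    per_fold: pd.DataFrame               # fold, auc, acc
    pooled_predictions: pd.DataFrame     # id, label, probability, prediction
    pooled_cm: ConfusionMatrix
    pooled_auc: float
    meta: dict = field(default_factory=dict)

    def pooled_metrics(self) -> MetricSet:
        return metrics(self.pooled_cm, auc=self.pooled_auc)


def kfold_split(n: int, k: int = 10, seed: int = 0,
                labels=None) -> np.ndarray:
    """Fold index (1..k) per sample; stratified by label when possible.

    A class with fewer than k members triggers an unstratified fallback
    with a warning.  Fold sizes differ by at most one per class.
    """
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    assignment = np.zeros(n, dtype=int)
    if labels is not None:
        labels = np.asarray(labels)
        if np.bincount(labels.astype(int), minlength=2).min() >= k:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=seed)
            for f, (_, test) in enumerate(
                    splitter.split(np.zeros((n, 1)), labels), start=1):
                assignment[test] = f
            return assignment
        warnings.warn("a class has fewer members than folds; "
                      "falling back to unstratified folds",
                      RuntimeWarning, stacklevel=2)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test) in enumerate(splitter.split(np.zeros((n, 1))), start=1):
        assignment[test] = f
    return assignment


def cross_validate_all(X: pd.DataFrame, y, methods=("logistic", "svm",
                                                    "adaboost"),
                       k: int = 10, seed: int = 0, select: bool = True,
                       n_lambda: int = 30, min_ratio: float = 0.05,
                       inner_folds: int = 5,
                       classifier_kwargs: dict | None = None,
                       ) -> dict[str, CVResult]:
    """k-fold CV of several methods sharing the per-fold preprocessing.

    Inside each training fold the features are standardized and the lasso
    selection is refit (inner CV for the penalty uses ``inner_folds`` folds
    over an ``n_lambda``-point grid); the held-out fold is transformed with
    the training fold's parameters only.  Running the methods together
    means the expensive selection happens once per fold instead of once per
    method per fold.
    """
    y = np.asarray(y).astype(int)
    ids = (X.index.to_numpy() if isinstance(X.index, pd.Index)
           else np.arange(len(y)))
    classifier_kwargs = classifier_kwargs or {}
    assignment = kfold_split(len(y), k=k, seed=seed, labels=y)

    proba = {m: np.full(len(y), np.nan) for m in methods}
    score = {m: np.full(len(y), np.nan) for m in methods}
    per_fold_rows: dict[str, list] = {m: [] for m in methods}
    selected_per_fold: list[int] = []

    for f in range(1, k + 1):
        test = assignment == f
        train = ~test
        X_tr, rec = _select.standardize(X.loc[train])
        X_te = rec.transform(X.loc[test])
        if select:
            keep = [c for c in X_tr.columns if c not in rec.zero_variance]
            path = _select.fit_lasso_path(X_tr[keep], y[train],
                                           n_lambda=n_lambda,
                                           min_ratio=min_ratio)
            _select.choose_lambda(path, X_tr[keep], y[train],
                                  folds=inner_folds, seed=seed * 1000 + f)
            feats = path.selected_features
            selected_per_fold.append(len(feats))
            if not feats:
                # no informative features: score the fold with the
                # intercept-only model (base-rate probability, tied scores
                # -> fold AUC 0.5 by the ties convention)
                base = float(y[train].mean())
                for m in methods:
                    proba[m][test] = base
                    score[m][test] = float(np.log(base / (1.0 - base)))
                    fold_acc = float(np.mean(int(base >= 0.5) == y[test]))
                    per_fold_rows[m].append((f, 0.5, fold_acc))
                continue
            X_tr, X_te = X_tr[feats], X_te[feats]
        for m in methods:
            kwargs = dict(classifier_kwargs.get(m, {}))
            if m in ("svm",):
                kwargs.setdefault("seed", seed * 1000 + f)
            try:
                model = _classify.train(m, X_tr, y[train], **kwargs)
            except Exception as exc:
                raise RuntimeError(f"fold {f}: training {m} failed: {exc}"
                                   ) from exc
            p = model.predict_proba(X_te)
            proba[m][test] = p
            # decision scores are monotone in p but never saturate in
            # floating point, so ROC ranking survives extreme fits
            s_te = model.decision_scores(X_te)
            score[m][test] = s_te
            fold_auc = roc_auc(y[test], s_te).auc
            fold_acc = float(np.mean((p >= 0.5).astype(int) == y[test]))
            per_fold_rows[m].append((f, fold_auc, fold_acc))

    results = {}
    for m in methods:
        p = proba[m]
        pred = (p >= 0.5).astype(int)
        results[m] = CVResult(
            method=m,
            fold_assignments=pd.Series(assignment, index=ids, name="fold"),
            per_fold=pd.DataFrame(per_fold_rows[m],
                                  columns=["fold", "auc", "acc"]),
            pooled_predictions=pd.DataFrame(
                {"label": y, "probability": p, "score": score[m],
                 "prediction": pred},
                index=ids),
            pooled_cm=confusion(y, pred, positive_label=1),
            pooled_auc=roc_auc(y, score[m]).auc,
            meta={"k": k, "seed": seed, "select": select,
                  "selected_per_fold": selected_per_fold})
    return results


def cross_validate(method: str, X: pd.DataFrame, y, k: int = 10,
                   seed: int = 0, **kwargs) -> CVResult:
    """k-fold CV of a single method (see :func:`cross_validate_all`)."""
    return cross_validate_all(X, y, methods=(method,), k=k, seed=seed,
                              **kwargs)[method]
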