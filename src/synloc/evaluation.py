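"""Performance metrics and repeated stratified cross-validation.

Threshold metrics follow the standard confusion-matrix definitions:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A probability >= threshold predicts the positive class.  Zero-denominator
ratios return 0 and set a degenerate flag (keeps pooled means defined).

ROC-AUC is the tie-corrected Mann-Whitney rank statistic; PR-AUC uses the
step-wise (average-precision) estimator, which avoids the optimistic bias
of linear interpolation in precision-recall space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .types import FeatureMatrix, LabeledDataset
from . import features as feat
from . import models as mod


@dataclass(frozen=True)
class ConfusionCounts:
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


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    roc_auc: float | None = None
    pr_auc: float | None = None
    degenerate: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1, "mcc": self.mcc,
            "roc_auc": self.roc_auc, "pr_auc": self.pr_auc,
            "degenerate": list(self.degenerate),
        }


def confusion(labels, probabilities, threshold: float = 0.5
              ) -> ConfusionCounts:
    """Tabulate TP/TN/FP/FN; probability >= threshold predicts positive."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    pred = p >= threshold
    return ConfusionCounts(
        tp=int(((y == 1) & pred).sum()),
        tn=int(((y == 0) & ~pred).sum()),
        fp=int(((y == 0) & pred).sum()),
        fn=int(((y == 1) & ~pred).sum()),
    )


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_confusion(c: ConfusionCounts) -> MetricSet:
    """Threshold metrics from a confusion table (AUCs not included)."""
    flags: list[str] = []
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy", flags)
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity", flags)
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity", flags)
    precision = _ratio(c.tp, c.tp + c.fp, "precision", flags)
    recall = sensitivity
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", flags)
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(accuracy, sensitivity, specificity, f1, mcc,
                     degenerate=tuple(flags))


def roc_auc(labels, scores) -> float:
    """ROC-AUC via the tie-corrected Mann-Whitney rank statistic."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined for single-class labels")
    ranks = rankdata(s)  # average ranks handle ties (= 1/2 credit)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_auc(labels, scores) -> float:
    """PR-AUC by step interpolation over recall (average precision)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("PR-AUC undefined for single-class labels")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # evaluate at each distinct threshold (tied scores enter together)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    n_pred = distinct + 1
    precision = tp / n_pred
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class CVResult:
    """Per-fold metrics plus pooled summaries from repeated stratified CV."""

    fold_metrics: pd.DataFrame  # columns: repetition, fold, metric values
    oof_probabilities: pd.DataFrame  # instances x repetitions
    repetitions: int
    folds: int

    @property
    def summary_mean(self) -> pd.Series:
        return self.fold_metrics.drop(columns=["repetition", "fold"]).mean()

    @property
    def summary_std(self) -> pd.Series:
        return self.fold_metrics.drop(columns=["repetition", "fold"]).std()

    @property
    def pooled_roc_auc(self) -> float:
        return float(self.summary_mean["roc_auc"])


def repeated_cv(spec: mod.ModelSpec, data: LabeledDataset,
                repetitions: int = 5, folds: int = 10,
                seed: int = 0, threshold: float = 0.5,
                scale: bool = True) -> CVResult:
    """Repeated stratified k-fold CV with in-fold scaling and balancing.

    The min-max scaler is fitted on each training fold only and applied
    (with clipping) to the held-out fold; for the ``ann1`` family the
    training fold is additionally bootstrap-balanced.  Pooled metrics are
    the mean over all repetitions x folds fold-level metrics.
    """
    y = data.labels
    counts = y.value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()}) is smaller than folds={folds}"
        )
    ids = np.asarray(y.index)
    rows = []
    oof = pd.DataFrame(index=y.index,
                       columns=[f"rep{r}" for r in range(repetitions)],
                       dtype=float)
    for rep in range(repetitions):
        cv = StratifiedKFold(n_splits=folds, shuffle=True,
                             random_state=seed + rep)
        for fold, (tr, te) in enumerate(cv.split(ids, y.to_numpy())):
            tr_ids, te_ids = list(ids[tr]), list(ids[te])
            train_ds = data.subset_instances(tr_ids)
            test_fm = FeatureMatrix(data.features.values.loc[te_ids],
                                    data.features.kinds)
            if scale:
                scaler = feat.fit_minmax(train_ds.features)
                train_ds = LabeledDataset(
                    feat.apply_minmax(train_ds.features, scaler),
                    train_ds.labels)
                test_fm = feat.apply_minmax(test_fm, scaler)
            if spec.family == "ann1":
                train_ds = mod.bootstrap_balance(
                    train_ds, seed=seed * 1000 + rep * folds + fold)
            fold_spec = spec.with_seed(seed + rep)
            model = mod.train(fold_spec, train_ds)
            probs = mod.predict_proba(model, test_fm)
            oof.loc[te_ids, f"rep{rep}"] = probs.to_numpy()
            y_te = y.loc[te_ids].to_numpy()
            ms = metrics_from_confusion(confusion(y_te, probs, threshold))
            ms.roc_auc = roc_auc(y_te, probs)
            ms.pr_auc = pr_auc(y_te, probs)
            rows.append({"repetition": rep, "fold": fold,
                         **{k: v for k, v in ms.to_dict().items()
                            if k != "degenerate"}})
    fold_metrics = pd.DataFrame(rows)
    return CVResult(fold_metrics, oof, repetitions, folds)


def evaluate_independent(model: mod.TrainedModel, test: LabeledDataset,
                         threshold: float = 0.5,
                         scaler: feat.MinMaxScalerState | None = None
                         ) -> MetricSet:
    """Evaluate on an independent test set, refusing train/test overlap.

    Instance IDs shared with the training set raise (leakage guard).  On a
    single-class test set the threshold metrics are still computed, but
    the AUCs are undefined and left as ``None`` with a flag.
    """
    overlap = sorted(model.training_instance_ids
                     & set(test.features.instances))
    if overlap:
        raise ValueError(f"test set overlaps training instances: "
                         f"{overlap[:10]}")
    fm = test.features
    if scaler is not None:
        fm = feat.apply_minmax(fm, scaler)
    probs = mod.predict_proba(model, fm)
    y = test.labels.to_numpy()
    ms = metrics_from_confusion(confusion(y, probs, threshold))
    if len(np.unique(y)) < 2:
        ms.degenerate = ms.degenerate + ("roc_auc", "pr_auc")
    else:
        ms.roc_auc = roc_auc(y, probs)
        ms.pr_auc = pr_auc(y, probs)
    return ms
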