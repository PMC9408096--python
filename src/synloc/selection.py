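"""Random-forest importance scoring, top-N selection, and aggregation of
expression-feature importances over the (age stage, tissue) sample grid.

Importances are the forest's impurity-decrease scores (they sum to 1 per
fitted forest); a forest is fitted on every training fold of a repeated
stratified CV and per-feature means over all fits rank the features.
Permutation importance is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .types import LabeledDataset, SampleAnnotation


@dataclass
class ImportanceTable:
    """Per-fit importance scores (features x fits) and their means."""

    per_fit: pd.DataFrame

    @property
    def mean(self) -> pd.Series:
        return self.per_fit.mean(axis=1)


@dataclass
class ImportanceGrid:
    """(tissue x age stage) averaged importances, sorted by marginals."""

    grid: pd.DataFrame  # rows: tissue_code, columns: age_stage


def compute_importance(data: LabeledDataset, repetitions: int = 5,
                       folds: int = 10, seed: int = 0,
                       n_estimators: int = 100,
                       method: str = "impurity") -> ImportanceTable:
    """Mean RF importance over all repetitions x folds training fits."""
    if method not in ("impurity", "permutation"):
        raise ValueError(f"unknown importance method {method!r}")
    y = data.labels
    if y.value_counts().min() < folds:
        raise ValueError(
            f"smallest class ({y.value_counts().min()}) < folds={folds}")
    X = data.features.values
    ids = np.asarray(y.index)
    cols = {}
    for rep in range(repetitions):
        cv = StratifiedKFold(n_splits=folds, shuffle=True,
                             random_state=seed + rep)
        for fold, (tr, _te) in enumerate(cv.split(ids, y.to_numpy())):
            forest = RandomForestClassifier(
                n_estimators=n_estimators, class_weight="balanced",
                random_state=seed + rep, n_jobs=1)
            X_tr = X.iloc[tr].to_numpy(dtype=float)
            y_tr = y.iloc[tr].to_numpy(dtype=int)
            forest.fit(X_tr, y_tr)
            if method == "impurity":
                scores = forest.feature_importances_
            else:
                scores = permutation_importance(
                    forest, X_tr, y_tr, n_repeats=5,
                    random_state=seed + rep).importances_mean
            cols[f"rep{rep}_fold{fold}"] = scores
    per_fit = pd.DataFrame(cols, index=X.columns)
    return ImportanceTable(per_fit)


def select_top(table: ImportanceTable, n: int) -> list[str]:
    """Top-n feature names by mean importance; ties break lexicographically."""
    if n <= 0:
        raise ValueError("n must be positive")
    means = table.mean
    order = sorted(means.index, key=lambda f: (-means[f], f))
    return order[:n]


def aggregate_by_sample_metadata(table: ImportanceTable,
                                 samples: list[SampleAnnotation]
                                 ) -> ImportanceGrid:
    """Average expression-feature importances per (age stage, tissue) cell.

    Features are named by sample ID; features with exactly zero mean
    importance ("no importance score") are excluded from their cell's
    mean.  Rows and columns are sorted by descending marginal mean
    importance (stable, so all-tied marginals keep insertion order).
    """
    means = table.mean
    by_sample = {s.sample_id: s for s in samples}
    records = []
    for feature, score in means.items():
        ann = by_sample.get(feature)
        if ann is None or score == 0.0:
            continue
        records.append((ann.tissue_code, ann.age_stage, score))
    if not records:
        raise ValueError("no scored expression features match the samples")
    df = pd.DataFrame(records, columns=["tissue_code", "age_stage", "score"])
    # preserve first-appearance order for stable tie handling
    tissue_order = list(dict.fromkeys(df["tissue_code"]))
    age_order = list(dict.fromkeys(df["age_stage"]))
    grid = df.pivot_table(index="tissue_code", columns="age_stage",
                          values="score", aggfunc="mean")
    grid = grid.reindex(index=tissue_order, columns=age_order)
    row_marg = grid.mean(axis=1)
    col_marg = grid.mean(axis=0)
    rows = sorted(grid.index, key=lambda t: -row_marg[t])
    cols = sorted(grid.columns, key=lambda a: -col_marg[a])
    return ImportanceGrid(grid.loc[rows, cols])
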