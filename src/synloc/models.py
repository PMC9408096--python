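"""Uniform training/prediction contract over five classifier families.

Families: penalized logistic regression (``logreg``), a maximum-margin
kernel classifier with sigmoid-calibrated probabilities (``maxmargin``),
random forest (``random_forest``), gradient-boosted trees
(``gradient_boosted_trees``, xgboost), and a one-hidden-layer neural
network (``ann1``).  All are trained through :func:`train` and queried
through :func:`predict_proba`, which aligns feature columns by name.

Class imbalance is addressed by inverse-frequency class weights for all
families except ``ann1``, which instead relies on bootstrap resampling of
the minority class (see :func:`bootstrap_balance`); cross-validation
applies it inside each training fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .types import FeatureMatrix, LabeledDataset

FAMILIES = ("logreg", "maxmargin", "random_forest",
            "gradient_boosted_trees", "ann1")

# Allowed hyperparameters per family (defaults shown); grids live in
# config files, not here.
_SCHEMAS: dict[str, dict[str, Any]] = {
    "logreg": {"C": 1.0, "max_iter": 2000},
    "maxmargin": {"C": 1.0, "kernel": "rbf", "gamma": "scale",
                  "calibration_folds": 3},
    "random_forest": {"n_estimators": 100, "max_depth": None,
                      "max_features": "sqrt", "min_samples_leaf": 1},
    "gradient_boosted_trees": {"n_estimators": 100, "max_depth": 4,
                               "learning_rate": 0.1, "subsample": 1.0},
    "ann1": {"hidden_units": 32, "alpha": 1e-3, "learning_rate_init": 1e-3,
             "max_iter": 300},
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model configuration."""

    family: str
    hyperparameters: tuple[tuple[str, Any], ...] = ()
    class_weighting: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {FAMILIES}")
        schema = _SCHEMAS[self.family]
        unknown = [k for k, _ in self.hyperparameters if k not in schema]
        if unknown:
            raise ValueError(f"hyperparameters not in {self.family} schema: "
                             f"{unknown}")

    @classmethod
    def create(cls, family: str, hyperparameters: Mapping[str, Any] | None = None,
               class_weighting: bool = True, random_seed: int = 0) -> "ModelSpec":
        hp = tuple(sorted((hyperparameters or {}).items()))
        return cls(family, hp, class_weighting, random_seed)

    @property
    def params(self) -> dict[str, Any]:
        merged = dict(_SCHEMAS[self.family])
        merged.update(dict(self.hyperparameters))
        return merged

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.family, self.hyperparameters,
                         self.class_weighting, seed)


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: Any
    feature_names: list[str]
    training_instance_ids: frozenset[str]


def _build_estimator(spec: ModelSpec, y: np.ndarray) -> Any:
    p = spec.params
    weight = "balanced" if spec.class_weighting else None
    seed = spec.random_seed
    if spec.family == "logreg":
        return LogisticRegression(C=p["C"], max_iter=p["max_iter"],
                                  class_weight=weight)
    if spec.family == "maxmargin":
        base = SVC(C=p["C"], kernel=p["kernel"], gamma=p["gamma"],
                   class_weight=weight, random_state=seed)
        cv = StratifiedKFold(n_splits=p["calibration_folds"], shuffle=True,
                             random_state=seed)
        return CalibratedClassifierCV(base, method="sigmoid", cv=cv)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"], max_depth=p["max_depth"],
            max_features=p["max_features"],
            min_samples_leaf=p["min_samples_leaf"],
            class_weight=weight, random_state=seed, n_jobs=1)
    if spec.family == "gradient_boosted_trees":
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        spw = (n_neg / n_pos) if (spec.class_weighting and n_pos) else 1.0
        return XGBClassifier(
            n_estimators=p["n_estimators"], max_depth=p["max_depth"],
            learning_rate=p["learning_rate"], subsample=p["subsample"],
            scale_pos_weight=spw, random_state=seed, n_jobs=1,
            eval_metric="logloss", verbosity=0)
    if spec.family == "ann1":
        return MLPClassifier(
            hidden_layer_sizes=(p["hidden_units"],), alpha=p["alpha"],
            learning_rate_init=p["learning_rate_init"],
            max_iter=p["max_iter"], random_state=seed)
    raise AssertionError(spec.family)


def train(spec: ModelSpec, data: LabeledDataset) -> TrainedModel:
    """Fit one model; deterministic given ``spec.random_seed``."""
    X = data.features.values.to_numpy(dtype=float)
    y = data.labels.to_numpy(dtype=int)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    est = _build_estimator(spec, y)
    est.fit(X, y)
    return TrainedModel(spec, est, data.features.feature_names,
                        frozenset(data.features.instances))


def predict_proba(model: TrainedModel, features: FeatureMatrix) -> pd.Series:
    """Probability of the positive class, columns aligned by name."""
    missing = [f for f in model.feature_names if f not in features.feature_names]
    extra = [f for f in features.feature_names if f not in model.feature_names]
    if missing or extra:
        raise ValueError(f"feature mismatch: missing {missing[:5]}, "
                         f"extra {extra[:5]}")
    X = features.values[model.feature_names].to_numpy(dtype=float)
    classes = list(model.estimator.classes_)
    proba = model.estimator.predict_proba(X)[:, classes.index(1)]
    return pd.Series(proba, index=features.instances, name="p_positive")


def bootstrap_balance(data: LabeledDataset, seed: int) -> LabeledDataset:
    """Resample the minority class with replacement up to majority size.

    Applied to ``ann1`` training data (the other families use class
    weights).  With already-balanced input, the class designated minority
    (ties resolve to the positive class) is still resampled, keeping
    counts unchanged but re-drawing its instances.
    """
    rng = np.random.default_rng(seed)
    pos = data.labels.index[data.labels == 1]
    neg = data.labels.index[data.labels == 0]
    if len(pos) <= len(neg):
        minority, majority = pos, neg
    else:
        minority, majority = neg, pos
    resampled = rng.choice(np.asarray(minority), size=len(majority),
                           replace=True)
    order = list(majority) + list(resampled)
    values = data.features.values.loc[order].copy()
    labels = data.labels.loc[order].copy()
    # resampling duplicates instances; suffix positions to keep IDs unique
    new_index = [f"{g}#{i}" for i, g in enumerate(order)]
    values.index = new_index
    labels.index = new_index
    fm = FeatureMatrix(values, data.features.kinds.copy())
    return LabeledDataset(fm, labels)


def save_model(model: TrainedModel, outdir) -> None:
    """Serialize as a versioned archive: JSON spec + joblib state."""
    import json
    from pathlib import Path

    import joblib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = model.spec
    payload = {
        "format_version": 1,
        "family": spec.family,
        "hyperparameters": dict(spec.hyperparameters),
        "class_weighting": spec.class_weighting,
        "random_seed": spec.random_seed,
        "feature_names": model.feature_names,
        "training_instance_ids": sorted(model.training_instance_ids),
    }
    (outdir / "spec.json").write_text(json.dumps(payload, indent=1))
    joblib.dump(model.estimator, outdir / "state.joblib")


def load_model(indir) -> TrainedModel:
    import json
    from pathlib import Path

    import joblib

    indir = Path(indir)
    payload = json.loads((indir / "spec.json").read_text())
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model archive version in {indir}")
    spec = ModelSpec.create(payload["family"], payload["hyperparameters"],
                            payload["class_weighting"],
                            payload["random_seed"])
    estimator = joblib.load(indir / "state.joblib")
    return TrainedModel(spec, estimator, payload["feature_names"],
                        frozenset(payload["training_instance_ids"]))


def grid_search(spec_template: ModelSpec, grid: Mapping[str, Sequence[Any]],
                data: LabeledDataset, cv_folds: int = 5) -> ModelSpec:
    """Pick the grid point maximizing mean CV ROC-AUC.

    Ties break by first-in-grid order; the full grid's scores are returned
    on the chosen spec via logging (and available programmatically through
    :func:`grid_search_scores`).
    """
    best_spec, _ = _grid_search_impl(spec_template, grid, data, cv_folds)
    return best_spec


def grid_search_scores(spec_template: ModelSpec,
                       grid: Mapping[str, Sequence[Any]],
                       data: LabeledDataset, cv_folds: int = 5
                       ) -> list[tuple[dict[str, Any], float]]:
    return _grid_search_impl(spec_template, grid, data, cv_folds)[1]


def _grid_search_impl(spec_template, grid, data, cv_folds):
    from .evaluation import roc_auc  # local import avoids cycle

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    names = list(grid.keys())
    X_fm = data.features
    y = data.labels
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                         random_state=spec_template.random_seed)
    results: list[tuple[dict[str, Any], float]] = []
    best: tuple[float, int] | None = None
    for i, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        hp = dict(spec_template.hyperparameters)
        hp.update(dict(zip(names, combo)))
        spec = ModelSpec.create(spec_template.family, hp,
                                spec_template.class_weighting,
                                spec_template.random_seed)
        aucs = []
        idx = np.arange(len(y))
        for tr, te in cv.split(idx, y.to_numpy()):
            sub_train = data.subset_instances([y.index[j] for j in tr])
            model = train(spec, sub_train)
            te_ids = [y.index[j] for j in te]
            te_fm = FeatureMatrix(X_fm.values.loc[te_ids], X_fm.kinds)
            probs = predict_proba(model, te_fm)
            aucs.append(roc_auc(y.loc[te_ids].to_numpy(), probs.to_numpy()))
        score = float(np.mean(aucs))
        results.append((dict(zip(names, combo)), score))
        if best is None or score > best[0]:
            best = (score, i)
    chosen = results[best[1]][0]
    hp = dict(spec_template.hyperparameters)
    hp.update(chosen)
    best_spec = ModelSpec.create(spec_template.family, hp,
                                 spec_template.class_weighting,
                                 spec_template.random_seed)
    return best_spec, results
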