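import numpy as np
import pandas as pd
import pytest

import synloc.evaluation as ev
import synloc.models as mod
from conftest import make_planted_dataset
from synloc.types import FeatureMatrix, LabeledDataset


def separable_dataset(n=20, seed=0):
    return make_planted_dataset(n_per_class=n // 2, n_features=2,
                                n_signal=2, shift=8.0, seed=seed)


class TestModelSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            mod.ModelSpec.create("deep_transformer")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            mod.ModelSpec.create("logreg", {"n_trees": 5})

    def test_defaults_merged(self):
        spec = mod.ModelSpec.create("random_forest", {"n_estimators": 50})
        assert spec.params["n_estimators"] == 50
        assert spec.params["max_features"] == "sqrt"


@pytest.mark.parametrize("family", mod.FAMILIES)
class TestFamilyContract:
    """Shared contract all five classifier families must satisfy."""

    def test_separable_data_fits_perfectly(self, family):
        data = separable_dataset()
        model = mod.train(mod.ModelSpec.create(family, random_seed=1), data)
        probs = mod.predict_proba(model, data.features)
        assert ((probs >= 0) & (probs <= 1)).all()
        acc = ((probs >= 0.5).astype(int) == data.labels).mean()
        assert acc == 1.0

    def test_single_class_is_error(self, family):
        data = separable_dataset()
        bad = LabeledDataset(data.features,
                             pd.Series(1, index=data.labels.index))
        with pytest.raises(ValueError, match="single class"):
            mod.train(mod.ModelSpec.create(family), bad)

    def test_nan_features_are_error(self, family):
        data = separable_dataset()
        values = data.features.values.copy()
        values.iloc[0, 0] = np.nan
        bad = LabeledDataset(FeatureMatrix(values, data.features.kinds),
                             data.labels)
        with pytest.raises(ValueError, match="NaN"):
            mod.train(mod.ModelSpec.create(family), bad)

    def test_seeded_determinism(self, family):
        data = make_planted_dataset(n_per_class=30, n_features=10,
                                    n_signal=3, shift=1.0, seed=4)
        spec = mod.ModelSpec.create(family, random_seed=42)
        p1 = mod.predict_proba(mod.train(spec, data), data.features)
        p2 = mod.predict_proba(mod.train(spec, data), data.features)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)

    def test_column_reordering_is_identity(self, family):
        data = separable_dataset()
        model = mod.train(mod.ModelSpec.create(family, random_seed=0), data)
        fm = data.features
        reordered = FeatureMatrix(fm.values[fm.feature_names[::-1]],
                                  fm.kinds[fm.feature_names[::-1]])
        p1 = mod.predict_proba(model, fm)
        p2 = mod.predict_proba(model, reordered)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy())

    def test_unknown_column_is_error(self, family):
        data = separable_dataset()
        model = mod.train(mod.ModelSpec.create(family), data)
        values = data.features.values.rename(columns={"f000": "zz"})
        fm = FeatureMatrix(values,
                           data.features.kinds.rename({"f000": "zz"}))
        with pytest.raises(ValueError, match="mismatch"):
            mod.predict_proba(model, fm)

    def test_planted_signal_cv_auc(self, family):
        data = make_planted_dataset(n_per_class=60, n_features=20,
                                    n_signal=5, shift=2.0, seed=9)
        cv = ev.repeated_cv(mod.ModelSpec.create(family, random_seed=0),
                            data, repetitions=1, folds=5, seed=3)
        assert cv.pooled_roc_auc >= 0.9


class TestLabelPermutationNull:
    def test_shuffled_labels_give_chance_auc(self):
        """Label-permutation null: CV AUC centred on 0.5 over 50 shuffles."""
        data = make_planted_dataset(n_per_class=100, n_features=10,
                                    n_signal=3, shift=2.0, seed=2)
        rng = np.random.default_rng(123)
        in_band = 0
        aucs = []
        for _ in range(50):
            perm = pd.Series(rng.permutation(data.labels.to_numpy()),
                             index=data.labels.index)
            shuffled = LabeledDataset(data.features, perm)
            cv = ev.repeated_cv(mod.ModelSpec.create("logreg"), shuffled,
                                repetitions=1, folds=10, seed=7)
            auc = cv.pooled_roc_auc
            aucs.append(auc)
            in_band += 0.4 <= auc <= 0.6
        assert abs(np.mean(aucs) - 0.5) < 0.05
        assert in_band >= 45  # 95% of runs within the chance band


class TestClassWeighting:
    def test_weighting_does_not_reduce_sensitivity(self):
        """On an imbalanced set, inverse-frequency weights shift the model
        toward the minority (positive) class at threshold 0.5."""
        rng = np.random.default_rng(8)
        n_pos, n_neg = 15, 135
        X = rng.normal(0, 1, size=(n_pos + n_neg, 5))
        X[:n_pos, :2] += 1.0
        ids = [f"g{i}" for i in range(n_pos + n_neg)]
        names = [f"f{j}" for j in range(5)]
        fm = FeatureMatrix(pd.DataFrame(X, index=ids, columns=names),
                           pd.Series("expression", index=names))
        data = LabeledDataset(fm, pd.Series([1] * n_pos + [0] * n_neg,
                                            index=ids))
        sens = {}
        for weighting in (True, False):
            spec = mod.ModelSpec.create("logreg", class_weighting=weighting)
            probs = mod.predict_proba(mod.train(spec, data), fm)
            c = ev.confusion(data.labels, probs)
            sens[weighting] = ev.metrics_from_confusion(c).sensitivity
        assert sens[True] >= sens[False]


class TestBootstrapBalance:
    def test_minority_upsampled_to_majority(self):
        data = make_planted_dataset(n_per_class=30, seed=0)
        # drop positives to create 10/30 imbalance
        keep = list(data.labels.index[data.labels == 1][:10]) + \
            list(data.labels.index[data.labels == 0])
        unbal = data.subset_instances(keep)
        out = mod.bootstrap_balance(unbal, seed=5)
        assert out.n_positive == out.n_negative == 30

    def test_balanced_input_counts_unchanged(self):
        data = make_planted_dataset(n_per_class=20, seed=0)
        out = mod.bootstrap_balance(data, seed=5)
        assert out.n_positive == out.n_negative == 20

    def test_seed_determinism(self):
        data = make_planted_dataset(n_per_class=25, seed=1)
        keep = list(data.labels.index[data.labels == 1][:8]) + \
            list(data.labels.index[data.labels == 0])
        unbal = data.subset_instances(keep)
        a = mod.bootstrap_balance(unbal, seed=11)
        b = mod.bootstrap_balance(unbal, seed=11)
        assert list(a.features.values.index) == list(b.features.values.index)


class TestGridSearch:
    def test_single_point_grid(self):
        data = separable_dataset()
        spec = mod.grid_search(mod.ModelSpec.create("logreg"),
                               {"C": [0.5]}, data, cv_folds=3)
        assert dict(spec.hyperparameters)["C"] == 0.5

    def test_underfitting_point_loses(self):
        # a one-tree forest underfits the planted signal; 100 trees win
        data = make_planted_dataset(n_per_class=40, n_features=30,
                                    n_signal=2, shift=1.5, seed=6)
        grid = {"n_estimators": [1, 100]}
        scores = dict(
            (hp["n_estimators"], auc) for hp, auc in
            mod.grid_search_scores(mod.ModelSpec.create("random_forest"),
                                   grid, data, cv_folds=5))
        assert scores[100] > scores[1]
        spec = mod.grid_search(mod.ModelSpec.create("random_forest"),
                               grid, data, cv_folds=5)
        assert dict(spec.hyperparameters)["n_estimators"] == 100

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            mod.grid_search(mod.ModelSpec.create("logreg"), {},
                            separable_dataset())


class TestSerialization:
    def test_round_trip_predictions_identical(self, tmp_path):
        data = separable_dataset()
        model = mod.train(mod.ModelSpec.create("random_forest",
                                               random_seed=3), data)
        mod.save_model(model, tmp_path / "m")
        back = mod.load_model(tmp_path / "m")
        p1 = mod.predict_proba(model, data.features)
        p2 = mod.predict_proba(back, data.features)
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())
        assert back.training_instance_ids == model.training_instance_ids
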