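import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

import synloc.evaluation as ev
import synloc.models as mod
from conftest import make_planted_dataset
from oracles import metrics_oracle, roc_auc_oracle
from synloc.types import LabeledDataset


class TestConfusion:
    def test_basic(self):
        c = ev.confusion([1, 0], [0.9, 0.1])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_boundary_half_predicts_positive(self):
        c = ev.confusion([1, 0], [0.5, 0.5])
        assert (c.tp, c.fp) == (1, 1)

    def test_all_negative_predictions(self):
        c = ev.confusion([1, 1, 0], [0.1, 0.2, 0.3])
        assert c.tp == 0 and c.fp == 0 and c.fn == 2 and c.tn == 1

    def test_total_matches_instances(self):
        c = ev.confusion([1, 0, 1, 0, 1], [0.6, 0.6, 0.2, 0.1, 0.9])
        assert c.total == 5


class TestMetricsFromConfusion:
    def test_perfect_classifier(self):
        m = ev.metrics_from_confusion(ev.ConfusionCounts(5, 5, 0, 0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1, m.mcc) == \
            (1, 1, 1, 1, 1)

    def test_hand_computed_table(self):
        # TP=2 TN=3 FP=1 FN=4: acc 1/2, sens 1/3, spec 3/4, F1 4/9,
        # MCC = 2 / sqrt(3*6*4*7)
        m = ev.metrics_from_confusion(ev.ConfusionCounts(2, 3, 1, 4))
        assert m.accuracy == pytest.approx(0.5)
        assert m.sensitivity == pytest.approx(1 / 3)
        assert m.specificity == pytest.approx(3 / 4)
        assert m.f1 == pytest.approx(4 / 9)
        assert m.mcc == pytest.approx(2 / np.sqrt(3 * 6 * 4 * 7))

    def test_degenerate_zero_denominators_flagged(self):
        m = ev.metrics_from_confusion(ev.ConfusionCounts(0, 3, 0, 2))
        assert m.f1 == 0.0 and "precision" in m.degenerate

    def test_constant_predictor_mcc_zero(self):
        # everything predicted positive: MCC degenerate -> flagged 0
        m = ev.metrics_from_confusion(ev.ConfusionCounts(4, 0, 6, 0))
        assert m.mcc == 0.0 and "mcc" in m.degenerate

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_matches_exact_rational_oracle(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        m = ev.metrics_from_confusion(ev.ConfusionCounts(tp, tn, fp, fn))
        expected = metrics_oracle(tp, tn, fp, fn)
        for name, val in expected.items():
            assert getattr(m, name) == pytest.approx(val, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert ev.roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert ev.roc_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_interleaved_pairs(self):
        # pairs: (0.9>0.8), (0.9>0.2), (0.3<0.8), (0.3>0.2) -> 3/4
        assert ev.roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == 0.75
        assert roc_auc_oracle([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == 0.75

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            ev.roc_auc([1, 1], [0.2, 0.3])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        assert ev.roc_auc(y, s) == pytest.approx(roc_auc_oracle(y, s),
                                                 abs=1e-12)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert ev.pr_auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_matches_sklearn_average_precision(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.uniform(size=n), 2)
            assert ev.pr_auc(y, s) == pytest.approx(
                average_precision_score(y, s), abs=1e-12)


class TestRepeatedCV:
    def test_fold_structure_and_stratification(self):
        data = make_planted_dataset(n_per_class=50, n_features=5,
                                    n_signal=2, shift=1.0, seed=0)
        cv = ev.repeated_cv(mod.ModelSpec.create("logreg"), data,
                            repetitions=2, folds=10, seed=1)
        assert len(cv.fold_metrics) == 20
        # every instance appears exactly once per repetition
        assert cv.oof_probabilities.notna().all().all()
        # stratification: test folds are 5/5 by construction here
        y = data.labels
        for rep in range(2):
            probs = cv.oof_probabilities[f"rep{rep}"]
            assert probs.index.equals(y.index)

    def test_stratified_fold_class_ratio_within_one(self):
        # 37 pos / 63 neg: each fold's positive count must be 3 or 4
        data = make_planted_dataset(n_per_class=50, n_features=4,
                                    n_signal=1, shift=1.0, seed=3)
        drop = list(data.labels.index[data.labels == 1][:13])
        sub = data.subset_instances(
            [g for g in data.labels.index if g not in drop])
        from sklearn.model_selection import StratifiedKFold
        y = sub.labels
        cv = StratifiedKFold(10, shuffle=True, random_state=0)
        for _, te in cv.split(np.arange(len(y)), y.to_numpy()):
            n_pos = y.iloc[te].sum()
            assert n_pos in (3, 4)

    def test_class_smaller_than_folds_is_error(self):
        data = make_planted_dataset(n_per_class=30, seed=0)
        small = data.subset_instances(
            list(data.labels.index[data.labels == 1][:5])
            + list(data.labels.index[data.labels == 0]))
        with pytest.raises(ValueError, match="folds"):
            ev.repeated_cv(mod.ModelSpec.create("logreg"), small, folds=10)

    def test_planted_signal_recovery(self):
        data = make_planted_dataset(n_per_class=60, n_features=20,
                                    n_signal=5, shift=2.0, seed=5)
        cv = ev.repeated_cv(mod.ModelSpec.create("logreg"), data,
                            repetitions=2, folds=10, seed=2)
        assert cv.pooled_roc_auc >= 0.9

    def test_cross_check_roc_auc_against_sklearn(self):
        data = make_planted_dataset(n_per_class=30, n_features=8,
                                    n_signal=2, shift=1.0, seed=8)
        cv = ev.repeated_cv(mod.ModelSpec.create("logreg"), data,
                            repetitions=1, folds=5, seed=0)
        probs = cv.oof_probabilities["rep0"]
        ours = ev.roc_auc(data.labels.to_numpy(), probs.to_numpy())
        theirs = roc_auc_score(data.labels.to_numpy(), probs.to_numpy())
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestEvaluateIndependent:
    def _model_and_test(self):
        data = make_planted_dataset(n_per_class=40, n_features=6,
                                    n_signal=2, shift=2.0, seed=10)
        pos = list(data.labels.index[data.labels == 1])
        neg = list(data.labels.index[data.labels == 0])
        train_ids = pos[:30] + neg[:30]
        test_ids = pos[30:] + neg[30:]
        model = mod.train(mod.ModelSpec.create("logreg"),
                          data.subset_instances(train_ids))
        return model, data, train_ids, test_ids

    def test_overlap_with_training_is_error(self):
        model, data, train_ids, _ = self._model_and_test()
        with pytest.raises(ValueError, match="overlap"):
            ev.evaluate_independent(model, data.subset_instances(train_ids))

    def test_disjoint_test_metrics_computed(self):
        model, data, _, test_ids = self._model_and_test()
        m = ev.evaluate_independent(model, data.subset_instances(test_ids))
        assert 0 <= m.accuracy <= 1 and m.roc_auc is not None

    def test_single_class_test_has_no_aucs(self):
        model, data, _, test_ids = self._model_and_test()
        pos_only = [g for g in test_ids if data.labels[g] == 1]
        m = ev.evaluate_independent(model, data.subset_instances(pos_only))
        assert m.roc_auc is None and m.pr_auc is None
        assert "roc_auc" in m.degenerate
        assert 0 <= m.sensitivity <= 1
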