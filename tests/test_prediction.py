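"""Prediction pipeline: features, folds, confusion metrics, experiments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnohrv.prediction import (ALL_FEATURES, CLINICAL_FEATURES,
                                 ConfusionMatrix, ExperimentConfig,
                                 PerformanceMetrics, assemble_features,
                                 average_metrics, cv_report,
                                 feature_importance, kfold_split,
                                 metrics_from_confusion, relative_change,
                                 run_experiment, train_classifier,
                                 undersample_controls)


class TestAssembleFeatures:
    record = dict(subject_id="S1", age=60, gender="male", bmi=27.0, height=170,
                  waist_hip_ratio=90.0, smoking_status="never",
                  lifetime_cigarettes=0.0, diabetes="no", hypertension="yes",
                  ahi=8.0, rdi=25.0, tp=2300.0, lf=500.0, hf=300.0,
                  hfnorm=37.0, sdnn=64.0, rmssd=38.0, mse1=1.45, mse2=1.50,
                  mse10=1.56, mpe=5.6)

    def test_full_vector_has_21_ordered_entries(self):
        vec = assemble_features(self.record, "full")
        assert list(vec.index) == ALL_FEATURES
        assert len(vec) == 21
        assert vec["gender"] == 1.0 and vec["hypertension"] == 1.0

    def test_clinical_only_has_11_entries(self):
        vec = assemble_features(self.record, "clinical_only")
        assert list(vec.index) == CLINICAL_FEATURES
        assert len(vec) == 11

    def test_unknown_category_raises(self):
        bad = dict(self.record, smoking_status="vaping")
        with pytest.raises(ValueError, match="unknown category"):
            assemble_features(bad)

    def test_unknown_feature_set_raises(self):
        with pytest.raises(ValueError):
            assemble_features(self.record, "hrv_only")


class TestMetricsFromConfusion:
    def test_reconstructed_fold_one_row(self):
        """TP=11, FN=3, FP=2, TN=12 on a 14+14 test fold."""
        m = metrics_from_confusion(ConfusionMatrix(tp=11, fn=3, fp=2, tn=12))
        assert round(m.acc, 1) == 82.1
        assert round(m.tpr, 1) == 78.6
        assert round(m.tnr, 1) == 85.7
        assert round(m.ppv, 1) == 84.6
        assert round(m.f1, 1) == 81.5
        assert round(m.mcc, 2) == 0.64

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=10, fn=0, fp=0, tn=10))
        assert (m.acc, m.tpr, m.tnr, m.ppv, m.f1) == (100, 100, 100, 100, 100)
        assert m.mcc == pytest.approx(1.0)

    def test_fold_three_row_consistency(self):
        """With TPR=100 and TNR=71.4 on 14+14, PPV is forced to 14/18 and
        F1 to 87.5."""
        m = metrics_from_confusion(ConfusionMatrix(tp=14, fn=0, fp=4, tn=10))
        assert round(m.acc, 1) == 85.7
        assert round(m.tpr, 1) == 100.0
        assert round(m.tnr, 1) == 71.4
        assert round(m.ppv, 1) == 77.8
        assert round(m.f1, 1) == 87.5
        assert round(m.mcc, 2) == 0.75

    def test_zero_denominator_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="PPV"):
            m = metrics_from_confusion(ConfusionMatrix(tp=0, fn=5, fp=0, tn=5))
        assert m.ppv == 0.0 and m.mcc == 0.0

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_algebraic_invariants(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics_from_confusion(ConfusionMatrix(tp, fn, fp, tn))
        assert -1.0 <= m.mcc <= 1.0
        # F1 via PPV/TPR equals 2TP/(2TP+FP+FN) algebraically
        if 2 * tp + fp + fn > 0 and tp > 0:
            assert m.f1 == pytest.approx(100 * 2 * tp / (2 * tp + fp + fn))
        # ACC is the prevalence-weighted combination of TPR and TNR
        n_pos, n_neg = tp + fn, tn + fp
        if n_pos > 0 and n_neg > 0:
            expected = (n_pos * m.tpr + n_neg * m.tnr) / (n_pos + n_neg)
            assert m.acc == pytest.approx(expected)


class TestCVReportAveraging:
    def test_identical_folds_average_to_fold_value(self):
        cm = ConfusionMatrix(tp=10, fn=4, fp=3, tn=11)
        rep = cv_report([cm] * 5)
        assert rep.average == metrics_from_confusion(cm)

    def test_field_wise_mean(self):
        folds = [PerformanceMetrics(80, 80, 80, 80, 80, 0.6),
                 PerformanceMetrics(90, 70, 90, 70, 90, 0.4)]
        avg = average_metrics(folds)
        assert avg.acc == 85 and avg.mcc == pytest.approx(0.5)

    def test_single_fold_report_raises(self):
        with pytest.raises(ValueError):
            cv_report([ConfusionMatrix(1, 1, 1, 1)])


class TestRelativeChange:
    @pytest.mark.parametrize("new, ref, expected", [
        (81.4, 73.5, 10.7),
        (0.64, 0.46, 39.1),
        (50.0, 50.0, 0.0),
    ])
    def test_worked_examples(self, new, ref, expected):
        assert round(relative_change(new, ref), 1) == expected

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            relative_change(1.0, 0.0)


class TestKFoldSplit:
    @staticmethod
    def balanced_table(n=140):
        return pd.DataFrame({"cvd": [1] * (n // 2) + [0] * (n // 2),
                             "x": np.arange(n, dtype=float)})

    def test_stratified_folds_of_28_with_14_each(self):
        table = self.balanced_table(140)
        folds = kfold_split(table, k=5, seed=0)
        for _, test_idx in folds:
            assert len(test_idx) == 28
            assert table.iloc[test_idx]["cvd"].sum() == 14

    def test_partition_disjoint_and_complete(self):
        table = self.balanced_table(97 * 2)
        folds = kfold_split(table, k=5, seed=1)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(len(table)))

    def test_same_seed_same_split(self):
        table = self.balanced_table(60)
        a = kfold_split(table, k=5, seed=3)
        b = kfold_split(table, k=5, seed=3)
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_k_exceeding_n_raises(self):
        with pytest.raises(ValueError):
            kfold_split(self.balanced_table(6), k=10)


class TestUndersampleControls:
    @staticmethod
    def table(n_controls=300, n_cases=40, seed=0):
        rng = np.random.default_rng(seed)
        n = n_controls + n_cases
        return pd.DataFrame({
            "cvd": [0] * n_controls + [1] * n_cases,
            "age": rng.normal(60, 10, n),
            "sdnn": rng.normal(64, 12, n),
        })

    def test_full_size_subset_is_identity(self):
        t = self.table()
        subset, report = undersample_controls(t, 300, variables=["age", "sdnn"])
        assert len(subset) == 300
        assert (report["ks_d"] == 0).all()

    def test_subset_similar_to_parent(self):
        t = self.table()
        subset, report = undersample_controls(t, 40, seed=5,
                                              variables=["age", "sdnn"])
        assert len(subset) == 40
        assert (subset["cvd"] == 0).all()
        assert (report["ks_p"] > 0.05).all()
        assert (report["jsd"] < 0.15).all()

    def test_deterministic_given_seed(self):
        t = self.table()
        a, _ = undersample_controls(t, 40, seed=9, variables=["age"])
        b, _ = undersample_controls(t, 40, seed=9, variables=["age"])
        assert list(a.index) == list(b.index)

    def test_insufficient_controls_raise(self):
        with pytest.raises(ValueError):
            undersample_controls(self.table(n_controls=30), 50, variables=["age"])


class TestTrainClassifier:
    def test_separable_data_fits_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(10, 1, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        model = train_classifier(X, y, seed=0)
        assert (model.predict(X) == y).all()

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.normal(size=(20, 3)), np.zeros(20))

    def test_importance_single_informative_feature(self, rng):
        X = np.hstack([np.vstack([rng.normal(0, 1, (50, 1)),
                                  rng.normal(8, 1, (50, 1))]),
                       rng.normal(0, 1, (100, 2))])
        y = np.array([0] * 50 + [1] * 50)
        model = train_classifier(X, y, seed=0)
        imp = feature_importance(model, ["signal", "noise1", "noise2"])
        assert imp["relative_importance"].sum() == pytest.approx(1.0)
        assert imp.iloc[0]["feature"] == "signal"

    def test_importance_requires_fitted_model(self):
        with pytest.raises(ValueError):
            feature_importance(object(), ["a"])


class TestRunExperiment:
    def test_deterministic_given_seed(self, hrv_effect_features):
        cfg = ExperimentConfig(mode="long", seed=4,
                               xgb_params=dict(n_estimators=30))
        a = run_experiment(hrv_effect_features, cfg)
        b = run_experiment(hrv_effect_features, cfg)
        assert a.report.average == b.report.average
        pd.testing.assert_frame_equal(a.importance, b.importance)

    def test_short_mode_balances_groups(self, study_effect_cohort):
        from hypnohrv.prediction import build_feature_table
        feats = build_feature_table(study_effect_cohort)
        res = run_experiment(feats, ExperimentConfig(mode="short", seed=1))
        n_cases = int((feats["cvd"] == 1).sum())
        assert res.n_subjects == 2 * n_cases  # controls under-sampled to cases
        assert res.similarity is not None
        assert res.report.k == 5

    def test_signal_recovery_beats_chance(self, hrv_effect_features):
        cfg = ExperimentConfig(mode="long", seed=2,
                               xgb_params=dict(n_estimators=60))
        res = run_experiment(hrv_effect_features, cfg)
        assert res.report.average.acc > 60.0

    def test_clinical_only_at_chance_on_hrv_effect_cohort(self, hrv_effect_features):
        cfg = ExperimentConfig(mode="long", feature_set="clinical_only", seed=2,
                               xgb_params=dict(n_estimators=60))
        res = run_experiment(hrv_effect_features, cfg)
        assert abs(res.report.average.acc - 50.0) < 15.0
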