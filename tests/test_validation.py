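"""Split arithmetic, fold hygiene, and the classification/regression metric
suite (including the published-table arithmetic)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meatspec.classifiers import KNearestClassifier
from meatspec.synthetic_spectra import BEEF_OFFAL_TYPES, PORK_OFFAL_TYPES
from meatspec.validation import (
    ConfusionMatrix,
    LeakageError,
    accuracy_from_sensitivities,
    confusion_metrics,
    display_percent,
    error_rate_from_sensitivities,
    evaluate_model,
    kfold_indices,
    make_split,
    regression_metrics,
)


class TestSplit:
    def test_per_type_spectrum_counts_match_study_design(self, study):
        meta = study["dataset"].meta
        cal = study["split"].calibration_mask(meta)
        pred = study["split"].prediction_mask(meta)
        for t in BEEF_OFFAL_TYPES + PORK_OFFAL_TYPES:
            mask = (meta.offal_type == t).to_numpy()
            assert (mask & cal).sum() == 65
            assert (mask & pred).sum() == 35
        beef = meta.offal_type.isin(BEEF_OFFAL_TYPES).to_numpy()
        assert (beef & cal).sum() == 195 and (beef & pred).sum() == 105
        pork = meta.offal_type.isin(PORK_OFFAL_TYPES).to_numpy()
        assert (pork & cal).sum() == 195 and (pork & pred).sum() == 105

    def test_no_sample_spans_both_sides(self, study):
        split = study["split"]
        assert not set(split.calibration_ids) & set(split.prediction_ids)
        meta = study["dataset"].meta
        both = split.calibration_mask(meta) & split.prediction_mask(meta)
        assert not both.any()

    def test_calibration_holds_three_levels_prediction_the_rest(self, study):
        meta = study["dataset"].meta
        cal_fracs = set(np.round(meta.fraction[study["split"].calibration_mask(meta)], 3))
        pred_fracs = set(np.round(meta.fraction[study["split"].prediction_mask(meta)], 3))
        assert {0.1, 0.333, 0.5} <= cal_fracs
        assert {0.25, 0.666} <= pred_fracs
        assert not {0.25, 0.666} & cal_fracs


class TestKfold:
    def test_folds_partition_all_rows(self):
        labels = np.array(list("aabbbccccd") * 4)
        fold = kfold_indices(labels, 4, seed=1)
        assert fold.min() == 0 and fold.max() == 3
        assert (fold >= 0).all()

    def test_leave_one_out_gives_singletons(self):
        labels = np.array(["x"] * 6)
        fold = kfold_indices(labels, 6, seed=0)
        assert sorted(fold.tolist()) == list(range(6))

    def test_grouping_keeps_samples_together(self):
        labels = np.repeat(["a", "b"], 10)
        groups = np.repeat(np.arange(10), 2)
        fold = kfold_indices(labels, 3, seed=2, groups=groups)
        for g in range(10):
            assert len(set(fold[groups == g])) == 1

    def test_small_class_warns(self):
        with pytest.warns(UserWarning, match="best-effort"):
            kfold_indices(np.array(["a"] * 10 + ["b"]), 5, seed=0)

    def test_deterministic_under_seed(self):
        labels = np.array(list("abc") * 7)
        assert np.array_equal(kfold_indices(labels, 3, seed=9), kfold_indices(labels, 3, seed=9))


class TestConfusionMetrics:
    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]), np.array(["a", "b", "c"]))
        m = confusion_metrics(cm)
        assert np.allclose(m.sensitivity, 1.0) and np.allclose(m.specificity, 1.0)
        assert m.error_rate == 0.0 and m.accuracy == 1.0

    def test_three_class_table_arithmetic_calibration(self):
        # per-class sensitivities 100/97/100 % -> 1 % error, 99 % accuracy
        err = error_rate_from_sensitivities([1.00, 0.97, 1.00])
        assert display_percent(err) == 1
        acc = accuracy_from_sensitivities([1.00, 0.97, 1.00], [40, 195, 195])
        assert display_percent(acc) == 99

    def test_offal_table_arithmetic_prediction(self):
        # equal class sizes: accuracy equals mean sensitivity exactly
        sens = [0.71, 0.91, 0.89]
        assert display_percent(error_rate_from_sensitivities(sens)) == 16
        assert display_percent(accuracy_from_sensitivities(sens, [35, 35, 35])) == 84

    def test_empty_class_row_rejected(self):
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), np.array(["a", "b"]))
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics(cm)

    def test_specificity_counts_correct_rows_of_other_classes(self):
        counts = np.array([[8, 2], [1, 9]])
        m = confusion_metrics(ConfusionMatrix(counts, np.array(["a", "b"])))
        assert m.specificity[0] == pytest.approx(9 / 10)
        assert m.specificity[1] == pytest.approx(8 / 10)
        assert m.precision[0] == pytest.approx(8 / 9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        counts=st.lists(
            st.lists(st.integers(0, 40), min_size=3, max_size=3), min_size=3, max_size=3
        )
    )
    def test_error_rate_identity_holds_exactly(self, counts):
        counts = np.asarray(counts)
        counts += np.diag([1, 1, 1])  # guarantee non-empty rows
        m = confusion_metrics(ConfusionMatrix(counts, np.array(["a", "b", "c"])))
        assert m.error_rate + m.sensitivity.mean() == pytest.approx(1.0, abs=1e-15)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        rows=st.lists(st.lists(st.integers(0, 9), min_size=3, max_size=3), min_size=3, max_size=3)
    )
    def test_equal_class_sizes_make_accuracy_equal_mean_sensitivity(self, rows):
        counts = np.asarray(rows)
        # pad each row to the same total
        target = counts.sum(axis=1).max() + 3
        for i in range(3):
            counts[i, i] += target - counts[i].sum()
        m = confusion_metrics(ConfusionMatrix(counts, np.array(["a", "b", "c"])))
        assert m.accuracy == pytest.approx(m.sensitivity.mean(), abs=1e-12)


class TestRegressionMetrics:
    def test_perfect_fit(self):
        y = np.array([0.1, 0.4, 0.7])
        m = regression_metrics(y, y, "prediction")
        assert m.rmse == 0.0 and m.r2 == 1.0

    def test_mean_prediction_scores_zero_r2(self):
        y = np.array([0.0, 0.5, 1.0, 0.3])
        m = regression_metrics(y, np.full(4, y.mean()), "prediction")
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_four_point_example_matches_hand_arithmetic(self):
        y = np.array([0.0, 0.2, 0.4, 0.6])
        yhat = np.array([0.1, 0.2, 0.3, 0.7])
        m = regression_metrics(y, yhat, "prediction")
        sse = 0.01 + 0.0 + 0.01 + 0.01
        sst = 0.09 + 0.01 + 0.01 + 0.09
        assert m.rmse == pytest.approx(np.sqrt(sse / 4))
        assert m.r2 == pytest.approx(1 - sse / sst)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([0.5, 0.5], [0.4, 0.6])


class TestEvaluateModel:
    def _toy(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.standard_normal((30, 3)) + [6, 0, 0], rng.standard_normal((30, 3))]
        )
        y = np.array(["pos"] * 30 + ["neg"] * 30)
        return X, y

    def test_separable_data_scores_perfectly_in_all_blocks(self):
        X, y = self._toy()
        cal = np.zeros(60, dtype=bool)
        cal[:20] = cal[30:50] = True
        blocks = evaluate_model(
            lambda: KNearestClassifier(k=3), X, y, cal, ~cal, cv_k=5, seed=0
        )
        for name in ("calibration", "cross_validation", "prediction"):
            assert blocks[name].accuracy == 1.0

    def test_overlapping_masks_raise_leakage_error(self):
        X, y = self._toy()
        mask = np.ones(60, dtype=bool)
        with pytest.raises(LeakageError):
            evaluate_model(lambda: KNearestClassifier(k=1), X, y, mask, mask, cv_k=3, seed=0)

    def test_groups_spanning_the_split_raise_leakage_error(self):
        X, y = self._toy()
        cal = np.zeros(60, dtype=bool)
        cal[:30] = True
        groups = np.array([0] * 29 + [1, 1] + [2] * 29)  # group 1 straddles
        with pytest.raises(LeakageError, match="span"):
            evaluate_model(
                lambda: KNearestClassifier(k=1), X, y, cal, ~cal, cv_k=3, seed=0, groups=groups
            )

    def test_metrics_reproducible_under_seed(self):
        X, y = self._toy()
        cal = np.zeros(60, dtype=bool)
        cal[:20] = cal[30:50] = True
        a = evaluate_model(lambda: KNearestClassifier(k=3), X, y, cal, ~cal, cv_k=4, seed=7)
        b = evaluate_model(lambda: KNearestClassifier(k=3), X, y, cal, ~cal, cv_k=4, seed=7)
        assert np.allclose(a["cross_validation"].sensitivity, b["cross_validation"].sensitivity)
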