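import numpy as np
import pytest

from ecglearn import evaluation
from ecglearn.evaluation import (BinaryConfusion, ClassMetrics,
                                 confusion_from_predictions, kfold_plan,
                                 macro_average, metrics_from_confusion,
                                 reconstruct_confusion, roc_auc,
                                 round_half_up)


class TestConfusionFromPredictions:
    def test_perfect_predictions_have_no_errors(self):
        Y = np.array([[1, 0], [0, 1], [1, 1]])
        cm = confusion_from_predictions(Y, Y, 0)
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp == 2 and cm.tn == 1

    def test_positive_convention_swap(self):
        rng = np.random.default_rng(0)
        Y = (rng.random((30, 3)) < 0.4).astype(int)
        P = (rng.random((30, 3)) < 0.4).astype(int)
        a = confusion_from_predictions(Y, P, 1, positive_label="present")
        b = confusion_from_predictions(Y, P, 1, positive_label="absent")
        assert (a.tp, a.fn, a.fp, a.tn) == (b.tn, b.fp, b.fn, b.tp)
        assert a.swapped() == b

    def test_hand_enumerated_toy(self):
        Y = np.array([[1], [1], [0], [0]])
        P = np.array([[1], [0], [1], [0]])
        cm = confusion_from_predictions(Y, P, 0)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_from_predictions(np.zeros((0, 1)), np.zeros((0, 1)), 0)


class TestMetrics:
    def test_all_correct_toy(self):
        m = metrics_from_confusion(BinaryConfusion(tp=6, fn=0, fp=0, tn=4))
        assert m.accuracy == 100.0 and m.fscore == 100.0 and m.mcc == 100.0

    def test_accuracy_from_correct_counts(self):
        """2288 + 358 correct of 2965 gives 89.24% accuracy."""
        cm = reconstruct_confusion(2288, 358, 2965, 97.69, 57.46)
        m = metrics_from_confusion(cm)
        assert round_half_up(m.accuracy) == 89.24

    def test_reconstructed_matrix_metrics(self):
        """tp=1298, fn=59, fp=144, tn=1464: precision 90.01%, MCC 86.42%."""
        m = metrics_from_confusion(BinaryConfusion(tp=1298, fn=59, fp=144,
                                                   tn=1464))
        assert round_half_up(m.precision) == 90.01
        assert round_half_up(m.mcc) == 86.42

    def test_zero_denominator_returns_zero_with_warning(self):
        cm = BinaryConfusion(tp=0, fn=0, fp=0, tn=5)
        with pytest.warns(RuntimeWarning):
            m = metrics_from_confusion(cm)
        assert m.precision == 0.0 and m.sensitivity == 0.0

    def test_agrees_with_sklearn_on_random_matrices(self):
        """1000 random confusion matrices vs the scikit-learn oracle, 1e-10."""
        from sklearn.metrics import (accuracy_score, f1_score,
                                     matthews_corrcoef, precision_score,
                                     recall_score)

        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fn, fp, tn = rng.integers(1, 40, size=4)
            cm = BinaryConfusion(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn))
            y_true = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
            y_pred = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
            m = metrics_from_confusion(cm)
            assert m.accuracy == pytest.approx(
                100 * accuracy_score(y_true, y_pred), abs=1e-10)
            assert m.precision == pytest.approx(
                100 * precision_score(y_true, y_pred), abs=1e-10)
            assert m.sensitivity == pytest.approx(
                100 * recall_score(y_true, y_pred), abs=1e-10)
            assert m.specificity == pytest.approx(
                100 * recall_score(1 - y_true, 1 - y_pred), abs=1e-10)
            assert m.fscore == pytest.approx(
                100 * f1_score(y_true, y_pred), abs=1e-10)
            assert m.mcc == pytest.approx(
                100 * matthews_corrcoef(y_true, y_pred), abs=1e-10)


class TestReconstructConfusion:
    def test_known_summary_rows(self):
        cm = reconstruct_confusion(1298, 1464, 2965, 95.65, 91.04)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1298, 59, 144, 1464)
        cm = reconstruct_confusion(2288, 358, 2965, 97.69, 57.46)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2288, 54, 265, 358)

    def test_perfect_sensitivity_has_no_false_negatives(self):
        cm = reconstruct_confusion(10, 5, 15, 100.0, 100.0)
        assert cm.fn == 0 and cm.fp == 0

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            reconstruct_confusion(1298, 1464, 3000, 95.65, 91.04)

    def test_round_trip_reproduces_summary(self):
        """reconstruct then re-measure: sensitivity/specificity within 0.01pp."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            # keep sensitivity/specificity large enough that 2-decimal
            # rounding stays invertible (the operation's precondition)
            tp, tn = (int(v) for v in rng.integers(50, 500, size=2))
            fn = int(rng.integers(0, tp // 2))
            fp = int(rng.integers(0, tn // 2))
            m = metrics_from_confusion(BinaryConfusion(tp, fn, fp, tn))
            sens = round(m.sensitivity, 2)
            spec = round(m.specificity, 2)
            cm = reconstruct_confusion(tp, tn, tp + fn + fp + tn, sens, spec)
            m2 = metrics_from_confusion(cm)
            assert abs(m2.sensitivity - sens) < 0.01 + 1e-9
            assert abs(m2.specificity - spec) < 0.01 + 1e-9


class TestMacroAverage:
    def test_known_accuracy_row(self):
        ms = [ClassMetrics(a, 0, 0, 0, 0, 0)
              for a in (89.24, 96.16, 89.41, 93.15, 88.23)]
        assert round_half_up(macro_average(ms).accuracy) == 91.24

    def test_known_sensitivity_row(self):
        ms = [ClassMetrics(0, 0, s, 0, 0, 0)
              for s in (97.69, 99.89, 98.84, 95.65, 97.04)]
        assert round_half_up(macro_average(ms).sensitivity) == 97.82

    def test_identical_entries_are_fixed_point(self):
        m = ClassMetrics(90.0, 80.0, 70.0, 60.0, 75.0, 50.0)
        assert macro_average([m, m, m]) == m

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            macro_average([])


class TestKfoldPlan:
    def test_fold_sizes_for_2965(self):
        folds = kfold_plan(2965, 10, seed=0)
        sizes = sorted(np.bincount(folds).tolist())
        assert sizes == [296] * 5 + [297] * 5

    def test_singleton_folds_when_k_equals_n(self):
        folds = kfold_plan(7, 7, seed=1)
        assert sorted(np.bincount(folds).tolist()) == [1] * 7

    def test_seeded_determinism_and_coverage(self):
        a = kfold_plan(100, 10, seed=5)
        b = kfold_plan(100, 10, seed=5)
        np.testing.assert_array_equal(a, b)
        assert set(a.tolist()) == set(range(10))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_plan(5, 10)


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(1.0)

    def test_random_scores_give_auc_half(self):
        rng = np.random.default_rng(0)
        y = (rng.random(10000) < 0.5).astype(int)
        s = rng.random(10000)
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = (rng.random(300) < 0.4).astype(int)
        s = rng.random(300)
        _, a = roc_auc(y, s)
        _, b = roc_auc(y, np.exp(5 * s))
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        y = (rng.random(500) < 0.3).astype(int)
        s = rng.random(500) + 0.5 * y
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(5), np.random.default_rng(0).random(5))


class TestReports:
    def test_full_report_structure_and_writers(self, tmp_path):
        rng = np.random.default_rng(3)
        Y = (rng.random((50, 5)) < 0.4).astype(int)
        scores = np.clip(0.6 * Y + 0.2 + 0.2 * rng.random((50, 5)), 0, 1)
        pred = (scores >= 0.5).astype(int)
        rep = evaluation.evaluate_predictions(
            Y, pred, scores, ("NORM", "MI", "STTC", "CD", "HYP"))
        assert set(rep.per_class) == {"NORM", "MI", "STTC", "CD", "HYP"}
        # macro metrics equal arithmetic means of per-class metrics
        assert rep.macro.accuracy == pytest.approx(
            np.mean([m.accuracy for m in rep.per_class.values()]))
        evaluation.write_metrics_csv(rep, tmp_path / "t.csv")
        evaluation.write_report_json(rep, tmp_path / "t.json")
        import pandas as pd
        df = pd.read_csv(tmp_path / "t.csv")
        assert list(df["class"]) == ["NORM", "MI", "STTC", "CD", "HYP",
                                     "Average"]
        assert set(df.columns) >= {"accuracy", "precision", "sensitivity",
                                   "specificity", "fscore", "mcc"}
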