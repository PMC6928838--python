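"""Confusion matrices and metrics, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenmap import (
    ConfusionMatrix,
    confusion_matrix,
    evaluate,
    macro_accuracy,
    micro_metrics,
    normalize_rows,
    overall_accuracy,
)

# 3-class worked example: 10 labels, 7 correct.
TOY_TRUE = list("AAABBBBCCC")
TOY_PRED = list("AABBBBCCCA")
TOY_ORDER = ("A", "B", "C")


def brute_force_confusion(true, pred, order):
    """Oracle: explicit double loop over label sequences."""
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(true, pred):
        counts[order.index(t), order.index(p)] += 1
    return counts


def brute_force_macro_accuracy(counts):
    """Oracle: reduce each class to a binary problem and average the
    binary accuracies."""
    l = counts.shape[0]
    total = counts.sum()
    accs = []
    for i in range(l):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        accs.append((tp + tn) / total)
    return sum(accs) / l


class TestConfusionMatrix:
    def test_toy_tally(self):
        cm = confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER)
        assert cm.counts.tolist() == [[2, 1, 0], [0, 3, 1], [1, 0, 2]]
        assert cm.total == 10

    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(TOY_TRUE, TOY_TRUE, TOY_ORDER)
        assert np.array_equal(cm.counts, np.diag([3, 4, 3]))

    def test_empty_input_all_zero(self):
        cm = confusion_matrix([], [], TOY_ORDER)
        assert cm.counts.sum() == 0 and cm.total == 0

    def test_matches_brute_force_on_random_inputs(self, rng):
        order = tuple("ABCDE")
        for _ in range(20):
            n = int(rng.integers(1, 40))
            true = [order[i] for i in rng.integers(0, 5, n)]
            pred = [order[i] for i in rng.integers(0, 5, n)]
            cm = confusion_matrix(true, pred, order)
            assert np.array_equal(cm.counts, brute_force_confusion(true, pred, order))
            assert cm.total == n  # count conservation

    def test_tp_fn_fp_tn_partition_total(self):
        cm = confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER)
        assert ((cm.tp + cm.fn + cm.fp + cm.tn) == cm.total).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix(["A"], ["A", "B"], TOY_ORDER)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(["Z"], ["A"], TOY_ORDER)

    def test_csv_roundtrip(self, tmp_path):
        cm = confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER)
        cm.to_csv(tmp_path / "cm.csv")
        reread = ConfusionMatrix.read_csv(tmp_path / "cm.csv")
        assert np.array_equal(cm.counts, reread.counts)
        assert reread.class_order == TOY_ORDER


class TestAccuracies:
    def test_toy_overall_vs_macro_distinction(self):
        """The per-class binary reduction averages to 0.8 while the plain
        fraction correct is 0.7 — two genuinely different statistics."""
        cm = confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER)
        assert overall_accuracy(cm) == pytest.approx(0.7)
        assert macro_accuracy(cm) == pytest.approx(0.8)

    def test_diagonal_matrix_gives_one(self):
        cm = ConfusionMatrix(np.diag([4, 2, 9]), TOY_ORDER)
        assert overall_accuracy(cm) == 1.0
        assert macro_accuracy(cm) == 1.0

    def test_macro_matches_brute_force_on_random_8x8(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, (8, 8))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(counts, tuple("ABCDEFGH"))
            assert macro_accuracy(cm) == pytest.approx(brute_force_macro_accuracy(counts))

    def test_binary_macro_equals_overall(self, rng):
        """For l = 2 the one-vs-rest reduction is an algebraic identity
        with overall accuracy; checked by enumeration over small matrices."""
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        if a + b + c + d == 0:
                            continue
                        cm = ConfusionMatrix(np.array([[a, b], [c, d]]), ("X", "Y"))
                        assert macro_accuracy(cm) == pytest.approx(overall_accuracy(cm))

    def test_empty_matrix_errors(self):
        cm = ConfusionMatrix(np.zeros((3, 3), dtype=int), TOY_ORDER)
        with pytest.raises(ValueError, match="empty"):
            overall_accuracy(cm)
        with pytest.raises(ValueError, match="empty"):
            macro_accuracy(cm)


class TestMicroMetrics:
    def test_diagonal_is_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 1, 2]), TOY_ORDER)
        assert micro_metrics(cm) == (1.0, 1.0, 1.0)

    def test_toy_micro_identity(self):
        precision, recall, f1 = micro_metrics(confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER))
        assert precision == pytest.approx(0.7)
        assert recall == pytest.approx(0.7)
        assert f1 == pytest.approx(0.7)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_micro_identity_property(self, seed):
        """Single-label multiclass: micro precision = micro recall =
        trace/total for any confusion matrix."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, (8, 8))
        if counts.trace() == 0:
            counts[0, 0] = 1
        cm = ConfusionMatrix(counts, tuple("ABCDEFGH"))
        precision, recall, _ = micro_metrics(cm)
        assert precision == pytest.approx(recall, abs=1e-12)
        assert precision == pytest.approx(overall_accuracy(cm), abs=1e-12)

    def test_zero_denominator_errors(self):
        cm = ConfusionMatrix(np.zeros((3, 3), dtype=int), TOY_ORDER)
        with pytest.raises(ValueError):
            micro_metrics(cm)


class TestNormalizeRows:
    def test_diagonal_becomes_identity(self):
        cm = ConfusionMatrix(np.diag([4, 2, 9]), TOY_ORDER)
        assert np.allclose(normalize_rows(cm), np.eye(3))

    def test_rows_sum_to_one_or_zero(self, rng):
        counts = rng.integers(0, 20, (8, 8))
        counts[3] = 0  # a class absent from the test set
        norm = normalize_rows(ConfusionMatrix(counts, tuple("ABCDEFGH")))
        sums = norm.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)
        assert np.allclose(norm[3], 0.0)

    def test_toy_row_division(self):
        norm = normalize_rows(confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER))
        assert norm[0].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_diagonal_entries_are_recalls(self):
        cm = confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER)
        report = evaluate(cm)
        assert report.per_class_recall["A"] == pytest.approx(2 / 3)
        assert report.per_class_recall["B"] == pytest.approx(3 / 4)


class TestReport:
    def test_report_fields_in_unit_interval(self, rng):
        counts = rng.integers(0, 30, (8, 8)) + np.eye(8, dtype=int)
        report = evaluate(ConfusionMatrix(counts, tuple("ABCDEFGH")))
        for v in (report.overall_accuracy, report.macro_accuracy,
                  report.micro_precision, report.micro_recall, report.f1_micro):
            assert 0.0 <= v <= 1.0

    def test_report_json(self, tmp_path):
        report = evaluate(confusion_matrix(TOY_TRUE, TOY_PRED, TOY_ORDER))
        report.to_json(tmp_path / "metrics.json")
        import json

        data = json.loads((tmp_path / "metrics.json").read_text())
        assert data["overall_accuracy"] == pytest.approx(0.7)
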