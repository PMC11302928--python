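"""Metric and loss contracts against counting/straight-line oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (boundary_oracle, confusion_oracle, sobel_oracle,
                      tversky_oracle)
from gnet.exceptions import ConfigurationError, DataError, ShapeError
from gnet.losses_metrics import (BoundaryParams, ConfusionCounts,
                                 TverskyParams, boundary_loss, brats_regions,
                                 confusion_counts, dice_coefficient, evaluate,
                                 one_hot, precision_accuracy_dice, sensitivity,
                                 sobel_edges, specificity, tversky_loss)


def random_masks(rng, shape=(16, 16), k=4):
    return rng.integers(0, k, shape), rng.integers(0, k, shape)


class TestConfusionCounts:
    def test_identity_prediction(self, rng):
        truth = rng.integers(0, 4, (16, 16))
        c = confusion_counts(truth, truth, 2)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == int(np.sum(truth == 2))

    def test_complement_prediction(self):
        truth = np.array([[0, 1], [1, 0]])
        c = confusion_counts(truth, 1 - truth, 1)
        assert c.tp == 0 and c.tn == 0

    @pytest.mark.parametrize("k", range(4))
    def test_matches_pixel_loop(self, rng, k):
        truth, pred = random_masks(rng)
        c = confusion_counts(truth, pred, k)
        assert (c.tp, c.fp, c.fn, c.tn) == confusion_oracle(truth, pred, k)
        assert c.total == truth.size

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_counts(np.zeros((4, 4)), np.zeros((4, 5)), 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestRatioMetrics:
    def test_half_recall(self):
        # 6 tumor pixels in truth, prediction covers 3 of them
        truth = np.zeros((4, 4), int)
        truth[0, :4] = 1
        truth[1, :2] = 1
        pred = np.zeros((4, 4), int)
        pred[0, :3] = 1
        assert sensitivity(confusion_counts(truth, pred, 1)) == 0.5

    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 2, (8, 8))
        c = confusion_counts(truth, truth, 1)
        assert sensitivity(c) == 1.0
        assert specificity(c) == 1.0
        assert precision_accuracy_dice(c) == (1.0, 1.0, 1.0)

    def test_zero_overlap_and_all_positive(self):
        truth = np.eye(4, dtype=int)
        pred = 1 - truth
        assert sensitivity(confusion_counts(truth, pred, 1)) == 0.0
        pred_all = np.ones((4, 4), int)
        assert specificity(confusion_counts(truth, pred_all, 1)) == 0.0

    def test_worked_arithmetic(self):
        prec, acc, dice = precision_accuracy_dice(
            ConfusionCounts(tp=3, fp=3, fn=3, tn=7))
        assert prec == 0.5
        assert acc == 0.625
        assert dice == 0.5

    def test_dice_is_f1_of_precision_recall(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(1, 50, 4)
            c = ConfusionCounts(int(tp), int(fp), int(fn), int(tn))
            prec, _, dice = precision_accuracy_dice(c)
            rec = sensitivity(c)
            assert dice == pytest.approx(2 * prec * rec / (prec + rec))

    def test_set_cardinality_agreement(self, rng):
        """tp/(tp+fn) and tn/(tn+fp) equal |X1∩G1|/|G1| and |X0∩G0|/|G0|."""
        for _ in range(50):
            truth, pred = random_masks(rng, k=2)
            c = confusion_counts(truth, pred, 1)
            g1 = truth == 1
            x1 = pred == 1
            if g1.sum():
                assert sensitivity(c) == np.sum(x1 & g1) / np.sum(g1)
            if (~g1).sum():
                assert specificity(c) == np.sum(~x1 & ~g1) / np.sum(~g1)

    def test_empty_class_sentinels(self):
        empty = ConfusionCounts(tp=0, fp=0, fn=0, tn=16)
        assert sensitivity(empty) == 1.0  # truth empty, prediction agrees
        spurious = ConfusionCounts(tp=0, fp=3, fn=0, tn=13)
        assert sensitivity(spurious) == 0.0


class TestTverskyLoss:
    def test_exact_match_is_zero(self, rng):
        y = one_hot(rng.integers(0, 4, (8, 8)), 4)
        assert tversky_loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_totally_wrong_binary_prediction(self):
        truth = np.zeros((4, 4), int)
        truth[:2] = 1
        y_true = one_hot(truth, 2)
        y_pred = one_hot(1 - truth, 2)
        loss = tversky_loss(y_true, y_pred,
                            TverskyParams(alpha=0.7, beta=0.3, smooth=1.0))
        # TP = 0; each of the 16 pixels contributes one FN (its true channel)
        # and one FP (the wrongly asserted channel)
        assert loss == pytest.approx(1.0 - 1.0 / (0.7 * 16 + 0.3 * 16 + 1))

    def test_monotone_along_interpolation(self, rng):
        truth = rng.integers(0, 2, (8, 8))
        y_true = one_hot(truth, 2)
        y_wrong = one_hot(1 - truth, 2)
        values = [
            tversky_loss(y_true, (1 - t) * y_wrong + t * y_true)
            for t in np.linspace(0, 1, 11)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y_true = one_hot(rng.integers(0, 3, (6, 6)), 3)
        y_pred = rng.random((6, 6, 3))
        params = TverskyParams(alpha=0.6, beta=0.4, smooth=0.5)
        assert tversky_loss(y_true, y_pred, params) == pytest.approx(
            tversky_oracle(y_true, y_pred, 0.6, 0.4, 0.5), abs=1e-6)

    def test_reduces_to_soft_dice(self, rng):
        """alpha = beta = 0.5 with vanishing smooth gives 1 - soft Dice."""
        y_true = one_hot(rng.integers(0, 4, (8, 8)), 4)
        y_pred = rng.random((8, 8, 4))
        loss = tversky_loss(y_true, y_pred,
                            TverskyParams(alpha=0.5, beta=0.5, smooth=1e-9))
        tp = np.sum(y_true * y_pred)
        fp = np.sum((1 - y_true) * y_pred)
        fn = np.sum(y_true * (1 - y_pred))
        assert loss == pytest.approx(1 - 2 * tp / (2 * tp + fp + fn), abs=1e-6)

    def test_range_invariant(self, rng):
        for _ in range(20):
            y_true = one_hot(rng.integers(0, 4, (8, 8)), 4)
            y_pred = rng.random((8, 8, 4))
            assert 0.0 <= tversky_loss(y_true, y_pred) < 1.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            TverskyParams(alpha=-0.1)


class TestSobelEdges:
    def test_constant_image_has_no_edges(self):
        np.testing.assert_array_equal(sobel_edges(np.full((8, 8), 3.0)), 0.0)

    def test_vertical_step_hand_values(self):
        img = np.zeros((6, 6))
        img[:, 3:] = 1.0
        edges = sobel_edges(img)
        # interior pixels flanking the step: |Gx| = 4, Gy = 0
        for i in (2, 3):
            assert edges[i, 2] == pytest.approx(4.0)
            assert edges[i, 3] == pytest.approx(4.0)
        # interior pixel far from the step sees nothing
        assert edges[3, 1] == pytest.approx(0.0)

    def test_offset_invariance(self, rng):
        img = rng.random((8, 8))
        np.testing.assert_allclose(sobel_edges(img), sobel_edges(img + 5.0),
                                   atol=1e-4)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_hand_convolution(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((7, 7))
        np.testing.assert_allclose(sobel_edges(img), sobel_oracle(img),
                                   atol=1e-5)

    def test_multichannel_rejected(self):
        with pytest.raises(ShapeError):
            sobel_edges(np.zeros((4, 4, 3)))


class TestBoundaryLoss:
    def test_identical_inputs_give_zero(self, rng):
        y = one_hot(rng.integers(0, 4, (8, 8)), 4)
        assert boundary_loss(y, y) == 0.0

    def test_symmetry(self, rng):
        a = rng.random((8, 8, 3))
        b = rng.random((8, 8, 3))
        assert boundary_loss(a, b) == pytest.approx(boundary_loss(b, a))

    def test_matches_convolve_and_average_oracle(self, rng):
        y_true = one_hot(rng.integers(0, 2, (8, 8)), 2)
        y_pred = rng.random((8, 8, 2))
        assert boundary_loss(y_true, y_pred, BoundaryParams(1.0)) == \
            pytest.approx(boundary_oracle(y_true, y_pred, 1.0), abs=1e-6)

    def test_weight_scales_linearly(self, rng):
        a, b = rng.random((6, 6, 2)), rng.random((6, 6, 2))
        assert boundary_loss(a, b, BoundaryParams(2.5)) == pytest.approx(
            2.5 * boundary_loss(a, b, BoundaryParams(1.0)))


class TestBratsRegions:
    def test_background_only(self):
        wt, tc, et = brats_regions(np.zeros((8, 8), int))
        assert not wt.any() and not tc.any() and not et.any()

    def test_enhancing_pixel_in_all_regions(self):
        mask = np.zeros((4, 4), int)
        mask[1, 2] = 3
        wt, tc, et = brats_regions(mask)
        assert wt[1, 2] and tc[1, 2] and et[1, 2]

    def test_region_nesting_counts(self, rng):
        for _ in range(20):
            mask = rng.integers(0, 4, (16, 16))
            wt, tc, et = brats_regions(mask)
            assert et.sum() <= tc.sum() <= wt.sum()
            assert np.all(~et | tc) and np.all(~tc | wt)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            brats_regions(np.full((2, 2), 4))


class TestEvaluate:
    def test_argmax_identity_gives_perfect_metrics(self, rng):
        truth = rng.integers(0, 4, (16, 16))
        prob = one_hot(truth, 4) * 0.9 + 0.025
        report = evaluate(truth, prob)
        for metrics in report.per_class.values():
            assert all(v == 1.0 for v in metrics.values())
        assert all(v == 1.0 for v in report.composite_dice.values())

    def test_uniform_probs_tie_break_to_class_zero(self, rng):
        truth = rng.integers(0, 4, (8, 8))
        prob = np.full((8, 8, 4), 0.25)
        report = evaluate(truth, prob)
        pred = np.zeros((8, 8), int)  # documented tie rule
        c = confusion_counts(truth, pred, 0)
        assert report.per_class["background"]["sensitivity"] == sensitivity(c)

    def test_all_values_in_unit_interval(self, rng):
        for _ in range(50):
            truth = rng.integers(0, 4, (8, 8))
            prob = rng.random((8, 8, 4))
            prob /= prob.sum(axis=-1, keepdims=True)
            report = evaluate(truth, prob)
            values = ([v for m in report.per_class.values() for v in m.values()]
                      + list(report.macro.values())
                      + list(report.composite_dice.values()))
            assert all(0.0 <= v <= 1.0 for v in values)

    def test_report_round_trips_to_json_and_csv(self, rng, tmp_path):
        truth = rng.integers(0, 4, (8, 8))
        report = evaluate(truth, one_hot(truth, 4))
        path = tmp_path / "report.json"
        report.to_json(str(path))
        assert path.exists()
        row = report.to_csv_row()
        assert row["dice_wt"] == 1.0
        assert "macro_accuracy" in row


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_dice_symmetry_property(seed):
    """Dice is symmetric in its two mask arguments."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, (8, 8))
    b = rng.integers(0, 2, (8, 8))
    assert dice_coefficient(a, b) == pytest.approx(dice_coefficient(b, a))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 0.9))
def test_tversky_alpha_beta_tradeoff(seed, alpha):
    """Raising the FN weight cannot lower the loss when FN > 0."""
    rng = np.random.default_rng(seed)
    y_true = one_hot(rng.integers(0, 2, (8, 8)), 2)
    y_pred = rng.random((8, 8, 2))
    lo = tversky_loss(y_true, y_pred, TverskyParams(alpha=alpha, beta=0.3))
    hi = tversky_loss(y_true, y_pred, TverskyParams(alpha=alpha + 0.05, beta=0.3))
    assert hi >= lo - 1e-12
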