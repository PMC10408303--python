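"""Objective function: focal/smooth-L1 closed forms, matching, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weednet.boxes import concat_anchors, generate_anchors
from weednet.losses import (
    FocalParams,
    detection_loss,
    focal_loss,
    match_anchors,
    smooth_l1,
)


def centered_box(cx, cy, w, h):
    return np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])


class TestFocalLoss:
    @pytest.mark.parametrize(
        "p, y, alpha, gamma, expected",
        [
            (0.5, 1, 0.5, 0.0, 0.5 * np.log(2.0)),  # alpha-weighted CE
            (0.5, 1, 0.25, 2.0, 0.25 * 0.25 * np.log(2.0)),  # direct evaluation
            (0.5, 0, 0.25, 2.0, 0.75 * 0.25 * np.log(2.0)),  # negative branch
        ],
    )
    def test_closed_form_values(self, p, y, alpha, gamma, expected):
        got = focal_loss(p, y, FocalParams(alpha=alpha, gamma=gamma))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_confident_correct_prediction_vanishes(self):
        assert focal_loss(1.0, 1, FocalParams()) == pytest.approx(0.0, abs=1e-4)

    def test_gamma_zero_unit_alpha_t_is_cross_entropy(self):
        # alpha_t == 1 means alpha = 1 on positives, alpha = 0 on negatives
        grid = np.linspace(0.001, 0.999, 199)
        for y, alpha in ((1, 1.0), (0, 0.0)):
            ce = -np.log(grid) if y == 1 else -np.log(1.0 - grid)
            got = focal_loss(grid, y, FocalParams(alpha=alpha, gamma=0.0))
            assert np.abs(got - ce).max() < 1e-12

    def test_strictly_decreasing_in_pt(self):
        grid = np.linspace(0.01, 0.99, 99)
        vals = focal_loss(grid, 1, FocalParams())
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals >= 0)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            focal_loss(1.5, 1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocalParams(alpha=1.5)
        with pytest.raises(ValueError):
            FocalParams(gamma=-1.0)


class TestSmoothL1:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (3.0, 2.5), (-3.0, 2.5), (0.5, 0.125)])
    def test_values(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected)

    def test_continuity_and_smoothness_at_knee(self):
        eps = 1e-8
        assert smooth_l1(1.0) == pytest.approx(0.5)
        assert smooth_l1(1.0 - eps) == pytest.approx(smooth_l1(1.0 + eps), abs=1e-7)
        # one-sided derivatives both approach 1 at |x| = 1
        h = 1e-6
        left = (smooth_l1(1.0) - smooth_l1(1.0 - h)) / h
        right = (smooth_l1(1.0 + h) - smooth_l1(1.0)) / h
        assert left == pytest.approx(right, abs=1e-4)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=200, deadline=None)
    def test_even_and_monotone(self, a, b):
        assert smooth_l1(a) == pytest.approx(smooth_l1(-a))
        if abs(a) <= abs(b):
            assert smooth_l1(a) <= smooth_l1(b) + 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            smooth_l1(np.inf)


class TestMatching:
    def test_empty_ground_truth_all_negative(self):
        anchors = concat_anchors(generate_anchors((64, 64)))
        m = match_anchors(anchors, np.empty((0, 4)))
        assert m.npos == 0
        assert m.negative_mask.all()

    def test_threshold_bands(self):
        # one anchor, gts engineered to hit IoU 0.6 / 0.45 / 0.3
        anchor = centered_box(50, 50, 20, 20)[None]
        for overlap, expected in ((0.6, "pos"), (0.45, "ignore"), (0.3, "neg")):
            # nested gt with area ratio = target IoU
            side = 20 * np.sqrt(overlap)
            gt = centered_box(50, 50, side, side)[None]
            m = match_anchors(anchor, gt)
            state = m.states[0]
            if expected == "pos":
                assert state == 0
            elif expected == "neg":
                assert state == -1
            else:
                assert m.ignore_mask[0]

    def test_coincident_anchor_is_positive(self):
        anchors = concat_anchors(generate_anchors((64, 64)))
        gt = anchors[100][None]
        m = match_anchors(anchors, gt)
        assert m.states[100] == 0

    def test_iou_tie_takes_lowest_gt_index(self):
        anchor = centered_box(50, 50, 20, 20)[None]
        gt = np.stack([centered_box(40, 50, 20, 20), centered_box(60, 50, 20, 20)])
        m = match_anchors(anchor, gt, pos_iou=0.3)
        assert m.states[0] == 0


class TestDetectionLoss:
    @pytest.fixture()
    def setting(self):
        anchors = concat_anchors(generate_anchors((64, 64)))
        gt = np.stack([centered_box(20, 20, 30, 30), centered_box(48, 48, 24, 24)])
        labels = np.array([0, 1])
        return anchors, gt, labels

    def test_perfect_prediction_gives_zero_loss(self, setting):
        anchors, gt, labels = setting
        m = match_anchors(anchors, gt)
        from weednet.boxes import encode

        logits = np.full((len(anchors), 2), -40.0)
        deltas = np.zeros((len(anchors), 4))
        pos = np.nonzero(m.positive_mask)[0]
        for i in pos:
            logits[i, labels[m.states[i]]] = 40.0
            deltas[i] = encode(gt[m.states[i]], anchors[i])
        bundle, _, _ = detection_loss(logits, deltas, anchors, gt, labels)
        assert bundle.total == pytest.approx(0.0, abs=1e-4)

    def test_empty_image_has_zero_regression_and_finite_cls(self, setting):
        anchors, _, _ = setting
        logits = np.zeros((len(anchors), 2))
        deltas = np.zeros((len(anchors), 4))
        bundle, _, dd = detection_loss(
            logits, deltas, anchors, np.empty((0, 4)), np.empty(0, dtype=int)
        )
        assert bundle.reg == 0.0
        assert np.isfinite(bundle.cls)
        assert np.allclose(dd, 0.0)

    def test_total_is_cls_plus_reg(self, setting, rng):
        anchors, gt, labels = setting
        logits = rng.normal(size=(len(anchors), 2))
        deltas = rng.normal(size=(len(anchors), 4))
        bundle, _, _ = detection_loss(logits, deltas, anchors, gt, labels)
        assert bundle.total == pytest.approx(bundle.cls + bundle.reg)
        assert bundle.cls >= 0 and bundle.reg >= 0

    def test_gradients_match_finite_differences(self, setting, rng):
        anchors, gt, labels = setting
        sub = slice(0, 400)  # keep the numeric sweep cheap
        anchors = anchors[sub]
        logits = rng.normal(size=(len(anchors), 2))
        deltas = rng.normal(scale=0.3, size=(len(anchors), 4))
        _, dl, dd = detection_loss(logits, deltas, anchors, gt, labels)
        eps = 1e-5
        for arr, grad, probes in ((logits, dl, [(0, 0), (37, 1)]), (deltas, dd, [(2, 3)])):
            for idx in probes:
                arr[idx] += eps
                up, *_ = detection_loss(logits, deltas, anchors, gt, labels)
                arr[idx] -= 2 * eps
                dn, *_ = detection_loss(logits, deltas, anchors, gt, labels)
                arr[idx] += eps
                numeric = (up.total - dn.total) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, abs=1e-6)
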