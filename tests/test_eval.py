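"""Evaluation metrics: hand-built precision/recall cases, a brute-force AP
oracle, and the error-decomposition accounting identities."""

import numpy as np
import pytest

from leafdet.evaluate import (
    average_precision,
    decompose_errors,
    evaluate_detections,
    pairwise_iou,
)
from conftest import random_boxes


def brute_force_ap(confs, tps, n_gt):
    """Rank-by-rank PR-curve integration oracle (exact all-point area)."""
    order = np.argsort(-np.asarray(confs), kind="stable")
    tps = np.asarray(tps)[order]
    area = 0.0
    best_prec_at = []
    tp = fp = 0
    points = []
    for t in tps:
        tp += t
        fp += 1 - t
        points.append((tp / n_gt, tp / (tp + fp)))
    # all-point: integrate max precision at recall >= r over recall steps
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        if r > prev_r:
            p_max = max(p for rr, p in points[i:])
            area += (r - prev_r) * p_max
            prev_r = r
    return area


def gt_box(x=10, y=10, s=20, cls=0):
    return [x, y, x + s, y + s, cls]


def pred_box(x=10, y=10, s=20, conf=0.9, cls=0):
    return [x, y, x + s, y + s, conf, cls]


class TestEvaluate:
    def test_perfect_predictions(self):
        gts = {"a": np.array([gt_box(cls=0), gt_box(60, 60, 20, cls=1)])}
        preds = {"a": np.array([pred_box(conf=1.0), pred_box(60, 60, 20, 1.0, 1)])}
        r = evaluate_detections(preds, gts)
        assert r.precision == 100 and r.recall == 100 and r.map50 == 100

    def test_half_right(self):
        """2 GT, one correct detection + one off-target -> P = R = 50%."""
        gts = {"a": np.array([gt_box(), gt_box(60, 60)])}
        preds = {"a": np.array([pred_box(conf=0.9),
                                pred_box(100, 100, 10, 0.8)])}
        r = evaluate_detections(preds, gts)
        # over all predictions (the plain TP/FP/FN counting rule)
        assert r.precision_all == 50 and r.recall_all == 50
        # the max-F1 operating point instead discards the weak off-target box
        assert r.precision == 100 and r.recall == 50

    def test_empty_everything_vacuous(self):
        r = evaluate_detections({}, {})
        assert r.map50 == 100 and r.precision == 100 and r.recall == 100

    def test_empty_preds_with_gt(self):
        r = evaluate_detections({}, {"a": np.array([gt_box()])})
        assert r.map50 == 0 and r.recall == 0

    def test_ap_matches_brute_force_oracle(self, rng):
        """Random 20-box case, AP vs independent PR integration."""
        for trial in range(20):
            n_gt = int(rng.integers(3, 8))
            n_p = 20
            tps_raw = rng.random(n_p) < 0.4
            # at most n_gt true positives
            idx = np.where(tps_raw)[0][:n_gt]
            tp = np.zeros(n_p, int)
            tp[idx] = 1
            confs = rng.random(n_p)
            order = np.argsort(-confs, kind="stable")
            got = average_precision(tp[order], n_gt)
            want = brute_force_ap(confs, tp, n_gt)
            assert got == pytest.approx(want, abs=1e-9)

    def test_map_invariant_to_monotone_conf_rescale(self, rng):
        gts = {"a": np.array([gt_box(), gt_box(60, 60)]),
               "b": np.array([gt_box(30, 30, 15, cls=1)])}
        preds = {
            "a": np.array([pred_box(conf=0.9), pred_box(62, 58, 20, 0.4),
                           pred_box(100, 100, 10, 0.6)]),
            "b": np.array([pred_box(31, 29, 15, 0.7, 1)]),
        }
        base = evaluate_detections(preds, gts).map50
        rescaled = {
            k: np.c_[v[:, :4], v[:, 4] ** 3 * 0.5, v[:, 5]] for k, v in preds.items()
        }
        assert evaluate_detections(rescaled, gts).map50 == pytest.approx(base)

    def test_duplicate_of_tp_never_raises_ap(self):
        gts = {"a": np.array([gt_box()])}
        preds = {"a": np.array([pred_box(conf=0.9)])}
        base = evaluate_detections(preds, gts).map50
        dup = {"a": np.array([pred_box(conf=0.9), pred_box(conf=0.8)])}
        assert evaluate_detections(dup, gts).map50 <= base

    def test_confusion_row_sums(self):
        gts = {"a": np.array([gt_box(cls=0), gt_box(60, 60, 20, cls=1)])}
        preds = {"a": np.array([pred_box(conf=0.9, cls=0),
                                pred_box(60, 60, 20, 0.8, 0),  # wrong class
                                pred_box(120, 5, 10, 0.7, 1)])}  # background
        r = evaluate_detections(preds, gts, confusion_conf=0.25)
        cm = r.confusion_matrix
        # row sums over predicted classes equal the prediction counts
        assert cm[0].sum() == 2 and cm[1].sum() == 1

    def test_one_gt_once(self):
        """A single GT can satisfy only one of two overlapping predictions."""
        gts = {"a": np.array([gt_box()])}
        preds = {"a": np.array([pred_box(conf=0.9), pred_box(11, 10, 20, 0.8)])}
        r = evaluate_detections(preds, gts)
        assert r.per_class_ap[0] == 100  # rank-1 TP; duplicate is FP after
        assert r.n_predictions == 2


class TestPairwiseIoU:
    def test_matches_scalar(self, rng):
        from leafdet.boxes import iou_breakdown

        a = random_boxes(rng, 15)
        b = random_boxes(rng, 10)
        m = pairwise_iou(a, b)
        for i in (0, 7, 14):
            for j in (0, 5, 9):
                assert m[i, j] == pytest.approx(iou_breakdown(a[i], b[j]).iou, abs=1e-9)


class TestDecomposition:
    def test_perfect_zero_errors(self):
        gts = {"a": np.array([gt_box()])}
        preds = {"a": np.array([pred_box(conf=0.95)])}
        d = decompose_errors(preds, gts, with_delta_map=False)
        assert (d.e_cls, d.e_loc, d.e_bkg, d.e_dup, d.e_miss, d.e_fp, d.e_fn) == (0,) * 7

    def test_wrong_class_high_iou(self):
        """One high-IoU wrong-class prediction: Ecls=1, EFP=1, EFN=1."""
        gts = {"a": np.array([gt_box(cls=0)])}
        preds = {"a": np.array([pred_box(conf=0.9, cls=1)])}
        d = decompose_errors(preds, gts, with_delta_map=False)
        assert d.e_cls == 1 and d.e_fp == 1 and d.e_fn == 1
        assert d.e_miss == 0  # the GT was covered, just misclassified

    def test_localization_error(self):
        gts = {"a": np.array([gt_box(10, 10, 20)])}
        preds = {"a": np.array([pred_box(18, 18, 20, 0.9)])}  # IoU ~ 0.2
        d = decompose_errors(preds, gts, with_delta_map=False)
        assert d.e_loc == 1 and d.e_bkg == 0 and d.e_fp == 1

    def test_background_error_and_miss(self):
        gts = {"a": np.array([gt_box()])}
        preds = {"a": np.array([pred_box(100, 100, 10, 0.9)])}
        d = decompose_errors(preds, gts, with_delta_map=False)
        assert d.e_bkg == 1 and d.e_miss == 1 and d.e_fn == 1

    def test_duplicate_error(self):
        gts = {"a": np.array([gt_box()])}
        preds = {"a": np.array([pred_box(conf=0.9), pred_box(conf=0.8)])}
        d = decompose_errors(preds, gts, with_delta_map=False)
        assert d.e_dup == 1 and d.e_fp == 1 and d.e_fn == 0

    def test_accounting_identities_randomized(self, rng):
        """EFP = Ecls + Eloc + Ebkg + Edup on 50 random cases."""
        for trial in range(50):
            n_img = int(rng.integers(1, 4))
            gts, preds = {}, {}
            for i in range(n_img):
                m = int(rng.integers(0, 5))
                k = int(rng.integers(0, 7))
                gts[i] = np.c_[random_boxes(rng, m), rng.integers(0, 3, m)] if m else np.zeros((0, 5))
                preds[i] = (
                    np.c_[random_boxes(rng, k), rng.random(k), rng.integers(0, 3, k)]
                    if k else np.zeros((0, 6))
                )
            d = decompose_errors(preds, gts, with_delta_map=False)
            assert d.e_fp == d.e_cls + d.e_loc + d.e_bkg + d.e_dup
            assert d.e_fn >= d.e_miss
            assert d.e_fn == sum(len(np.asarray(g).reshape(-1, 5)) for g in gts.values()) - (
                d.n_predictions - d.e_fp
            )

    def test_errors_shrink_as_predictions_approach_gt(self):
        """Interpolating predicted boxes toward GT cannot add errors."""
        rng = np.random.default_rng(1)
        g = random_boxes(rng, 6)
        gts = {"a": np.c_[g, np.zeros(6)]}
        start = random_boxes(rng, 6)
        prev_fp = None
        for t in (0.0, 0.5, 0.9, 1.0):
            boxes = (1 - t) * start + t * g
            preds = {"a": np.c_[boxes, np.full(6, 0.9), np.zeros(6)]}
            d = decompose_errors(preds, gts, with_delta_map=False)
            if prev_fp is not None:
                assert d.e_fp <= prev_fp
            prev_fp = d.e_fp
        assert prev_fp == 0

    def test_delta_map_estimates_signed_sensibly(self):
        gts = {"a": np.array([gt_box(), gt_box(60, 60)])}
        preds = {"a": np.array([pred_box(conf=0.9),
                                pred_box(100, 100, 10, 0.95)])}  # bkg FP above the TP
        d = decompose_errors(preds, gts)
        assert d.delta_map["e_bkg"] >= 0  # removing background FPs helps
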