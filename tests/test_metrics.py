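"""Metric formulas, AP integration, invariances and the small-object subset."""

import warnings

import numpy as np
import pytest

from pestlite.detect import Detection
from pestlite.metrics import (IOU_CUTS_50_95, average_precision,
                              compute_pr_f1_acc, evaluate_detections)


def det(img, box, cls=0, conf=0.9):
    return Detection(np.array(box, dtype=float), cls, conf, img)


# ---------------------------------------------------------------------------
# formula arithmetic
# ---------------------------------------------------------------------------

def test_precision_recall_examples():
    p, r, f1, acc = compute_pr_f1_acc(8, 2, 0, 0)
    assert p == pytest.approx(0.8)
    assert r == 1.0


def test_f1_equals_p_when_precision_matches_recall():
    p, r, f1, _ = compute_pr_f1_acc(3, 1, 0, 1)
    assert p == r == pytest.approx(0.75)
    assert f1 == pytest.approx(0.75)


def test_perfect_accuracy():
    *_, acc = compute_pr_f1_acc(5, 0, 5, 0)
    assert acc == 1.0


def test_zero_denominator_warns_and_returns_zero():
    with pytest.warns(UserWarning, match="undefined"):
        p, *_ = compute_pr_f1_acc(0, 0, 0, 3)
    assert p == 0.0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        compute_pr_f1_acc(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def test_perfect_detections_ap_one():
    gts = {0: np.array([[0, 0, 10, 10], [20, 20, 30, 30.0]])}
    dets = [det(0, [0, 0, 10, 10], conf=0.9), det(0, [20, 20, 30, 30], conf=0.8)]
    assert average_precision(dets, gts, 0.5) == pytest.approx(1.0)


def test_no_detections_ap_zero():
    assert average_precision([], {0: np.array([[0, 0, 5, 5.0]])}, 0.5) == 0.0


def test_no_ground_truth_warns_nan():
    with pytest.warns(UserWarning, match="no ground truth"):
        out = average_precision([det(0, [0, 0, 5, 5])], {0: np.zeros((0, 4))}, 0.5)
    assert np.isnan(out)


def test_toy_pr_curve_hand_integral():
    """3 detections, 2 GT: TP, FP, TP in confidence order.

    The precision envelope is 1.0 up to recall 0.5 and 2/3 beyond, so the
    101-point AP is (51·1 + 50·2/3) / 101.
    """
    gts = {0: np.array([[0, 0, 10, 10], [20, 20, 30, 30.0]])}
    dets = [det(0, [0, 0, 10, 10], conf=0.9),
            det(0, [40, 40, 50, 50], conf=0.8),
            det(0, [20, 20, 30, 30], conf=0.7)]
    expect = (51 * 1.0 + 50 * (2.0 / 3.0)) / 101
    assert average_precision(dets, gts, 0.5) == pytest.approx(expect)


def test_ap_invariant_to_detection_order():
    r = np.random.default_rng(0)
    gts = {i: np.sort(r.uniform(0, 50, (3, 4)).reshape(3, 2, 2), axis=1)
           .reshape(3, 4) + np.array([0, 0, 2, 2]) for i in range(4)}
    dets = [det(i, b + r.normal(0, 1, 4), conf=float(r.uniform(0.1, 1)))
            for i in range(4) for b in gts[i]]
    base = average_precision(dets, gts, 0.5)
    r.shuffle(dets)
    assert average_precision(dets, gts, 0.5) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def _toy_world():
    gt = {0: (np.array([[0, 0, 10, 10], [20, 20, 60, 60.0]]),
              np.array([0, 1])),
          1: (np.array([[5, 5, 15, 15.0]]), np.array([0]))}
    dets = [det(0, [0, 0, 10, 10], 0, 0.9),
            det(0, [21, 21, 59, 59], 1, 0.8),
            det(1, [5, 5, 15, 15], 0, 0.7)]
    return gt, dets


def test_report_ranges_and_counts():
    gt, dets = _toy_world()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = evaluate_detections(dets, gt, 3)
    assert rep.map50 == pytest.approx(1.0)
    assert rep.counts["TP"] == 3 and rep.counts["FP"] == 0
    assert 0 <= rep.accuracy <= 1


def test_small_subset_equivalence():
    """mAP_small equals plain AP computed on the small-only ground truth."""
    gt, dets = _toy_world()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = evaluate_detections(dets, gt, 2, small_threshold=20.0)
        small_gts = {0: np.array([[0, 0, 10, 10.0]]),
                     1: np.array([[5, 5, 15, 15.0]])}
        ap0 = average_precision([d for d in dets if d.class_id == 0],
                                small_gts, 0.5)
    assert rep.map_small == pytest.approx(ap0)


def test_all_large_gt_reports_absent_small_metrics():
    gt = {0: (np.array([[0, 0, 50, 50.0]]), np.array([0]))}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = evaluate_detections([det(0, [0, 0, 50, 50])], gt, 1,
                                  small_threshold=20.0)
    assert rep.map_small is None and rep.recall_small is None


def test_map50_95_averages_ten_cuts():
    assert len(IOU_CUTS_50_95) == 10
    gt = {0: (np.array([[0, 0, 20, 20.0]]), np.array([0]))}
    dets = [det(0, [0, 0, 20, 20], 0, 0.9)]          # exact: AP 1 at all cuts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = evaluate_detections(dets, gt, 1)
    assert rep.map50_95 == pytest.approx(1.0)


def test_metric_suite_agrees_with_brute_force_oracle():
    """20 random toy scenes: mAP@50 and mAP@50:95 within 1e-4 of the
    independent prefix-rematching evaluator."""
    from oracle_eval import oracle_map

    r = np.random.default_rng(42)
    n_cls = 3
    gt, dets = {}, []
    for img in range(20):
        m = int(r.integers(1, 5))
        boxes = []
        for _ in range(m):
            x0, y0 = r.uniform(0, 70, 2)
            w, h = r.uniform(5, 25, 2)
            boxes.append([x0, y0, x0 + w, y0 + h])
        boxes = np.array(boxes)
        labels = r.integers(0, n_cls, m)
        gt[img] = (boxes, labels)
        for b, l in zip(boxes, labels):
            if r.random() < 0.8:     # noisy true positive
                jit = b + r.normal(0, 2.0, 4)
                if jit[2] > jit[0] + 1 and jit[3] > jit[1] + 1:
                    dets.append(det(img, jit, int(l), float(r.uniform(0.3, 1))))
            if r.random() < 0.3:     # random false positive
                x0, y0 = r.uniform(0, 60, 2)
                dets.append(det(img, [x0, y0, x0 + 10, y0 + 10],
                                int(r.integers(0, n_cls)),
                                float(r.uniform(0.05, 1))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = evaluate_detections(dets, gt, n_cls)
    dets_by_class = {c: [(d.image_id, tuple(d.box), d.confidence)
                         for d in dets if d.class_id == c] for c in range(n_cls)}
    gts_by_class = {c: {img: [tuple(b) for b, l in zip(*gt[img]) if l == c]
                        for img in gt} for c in range(n_cls)}
    assert rep.map50 == pytest.approx(
        oracle_map(dets_by_class, gts_by_class, [0.5]), abs=1e-4)
    assert rep.map50_95 == pytest.approx(
        oracle_map(dets_by_class, gts_by_class, IOU_CUTS_50_95), abs=1e-4)
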