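"""Target assignment, losses, NMS and decoding."""

import numpy as np
import pytest

from pestlite import nn
from pestlite.data import box_iou
from pestlite.detect import (Detection, assign_and_loss, assign_targets,
                             decode_boxes, detection_loss, nms, nms_decode)

rng = np.random.default_rng(0)
SHAPES = {4: (16, 16), 8: (8, 8), 16: (4, 4)}


def test_small_boxes_assigned_to_stride4_only():
    boxes = np.array([[30.0, 30.0, 40.0, 40.0]])     # 10-px pest
    tgt = assign_targets(boxes, [0], SHAPES, 3)
    assert tgt[4][3].any()
    assert not tgt[8][3].any() and not tgt[16][3].any()


def test_large_boxes_escalate_levels():
    boxes = np.array([[4.0, 4.0, 60.0, 60.0]])       # 56-px lesion
    tgt = assign_targets(boxes, [2], SHAPES, 3)
    assert tgt[8][3].any() and not tgt[16][3].any()


def test_centerness_in_unit_range_and_peaks_at_center():
    boxes = np.array([[8.0, 8.0, 24.0, 24.0]])
    tgt = assign_targets(boxes, [0], SHAPES, 3)
    _, box_t, ctr_t, pos = tgt[4]
    assert ctr_t[pos].max() <= 1.0 and ctr_t[pos].min() >= 0.0


def test_exact_predictions_give_zero_regression_loss():
    boxes = np.array([[16.0, 16.0, 44.0, 44.0]])
    labels = [1]
    tgt = assign_targets(boxes, labels, SHAPES, 3)
    level_out = {}
    for s, (h, w) in SHAPES.items():
        cls_t, box_t, ctr_t, pos = tgt[s]
        cls = np.full((1, 3, h, w), -20.0)
        cls[0][cls_t.T.reshape(3, h, w) > 0] = 20.0
        reg = np.maximum(box_t.T.reshape(4, h, w)[None], 1e-3)
        t = np.clip(ctr_t, 1e-6, 1 - 1e-6)
        ctr = np.log(t / (1 - t)).reshape(1, 1, h, w)
        level_out[s] = (nn.Tensor(cls), nn.Tensor(reg), nn.Tensor(ctr))
    total, parts = detection_loss(level_out, [tgt], 3)
    assert parts["box"] == pytest.approx(0.0, abs=1e-6)
    assert np.isfinite(total.data)


def test_empty_image_gives_classification_only_loss():
    tgt = assign_targets(np.zeros((0, 4)), [], SHAPES, 3)
    level_out = {s: (nn.Tensor(rng.normal(size=(1, 3, h, w))),
                     nn.Tensor(np.ones((1, 4, h, w))),
                     nn.Tensor(rng.normal(size=(1, 1, h, w))))
                 for s, (h, w) in SHAPES.items()}
    total, parts = detection_loss(level_out, [tgt], 3)
    assert parts["box"] == 0.0 and parts["ctr"] == 0.0
    assert parts["cls"] > 0.0 and np.isfinite(total.data)


def test_loss_decreases_when_overfitting_head(trained_tiny_model,
                                              small_dataset):
    """End-to-end gradient sanity: a few steps on one batch reduce loss."""
    from pestlite.model import ModelConfig, build_model
    from pestlite.train import Trainer, TrainConfig

    model = build_model(ModelConfig(width_ratio=0.25, seed=2))
    cfg = TrainConfig(batch_size=4, lr=2e-3, epochs=6, augment=None, seed=0)
    tr = Trainer(model, cfg)
    hist = tr.fit(small_dataset[:4], None)
    assert hist[-1]["loss"] < hist[0]["loss"]


def test_nms_keeps_best_of_duplicates_and_disjoint_boxes():
    boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10], [30, 30, 40, 40.0]])
    scores = np.array([0.9, 0.8, 0.7])
    keep = nms(boxes, scores, 0.5)
    assert keep == [0, 2]


def test_nms_matches_brute_force_oracle():
    r = np.random.default_rng(4)
    for _ in range(20):
        boxes = np.sort(r.uniform(0, 40, size=(5, 4)).reshape(5, 2, 2),
                        axis=1).reshape(5, 4)
        boxes[:, 2:] += 1.0
        scores = r.uniform(0.1, 1.0, 5)
        got = set(nms(boxes, scores, 0.4))
        # oracle: explicit all-pairs sequential suppression
        order = np.argsort(-scores, kind="stable")
        kept = []
        for i in order:
            if all(box_iou(boxes[i][None], boxes[j][None])[0, 0] <= 0.4
                   for j in kept):
                kept.append(int(i))
        assert got == set(kept)


def test_decode_round_trips_distances():
    reg = np.zeros((1, 4, 2, 2))
    reg[0] = 4.0
    boxes = decode_boxes(reg, 8)
    cen = np.array([[4.0, 4.0], [12, 4], [4, 12], [12, 12.0]])
    assert np.allclose(boxes[:, :2], cen - 4.0)
    assert np.allclose(boxes[:, 2:], cen + 4.0)


def test_nms_decode_thresholds_validated_and_sorted():
    h = w = 4
    level = {8: (np.full((1, 2, h, w), 3.0), np.full((1, 4, h, w), 4.0),
                 np.full((1, 1, h, w), 3.0))}
    with pytest.raises(ValueError, match="thresholds"):
        nms_decode(level, conf_thresh=1.5)
    dets = nms_decode(level, conf_thresh=0.2, iou_thresh=0.5)
    confs = [d.confidence for d in dets]
    assert confs == sorted(confs, reverse=True)
    for d in dets:
        assert isinstance(d, Detection)


def test_detection_validation():
    with pytest.raises(ValueError, match="confidence"):
        Detection(np.array([0, 0, 2, 2]), 0, 1.4)
    with pytest.raises(ValueError, match="degenerate"):
        Detection(np.array([5, 5, 5, 9]), 0, 0.5)


def test_assign_and_loss_wrapper_runs():
    level_out = {s: (nn.Tensor(rng.normal(size=(2, 3, h, w))),
                     nn.Tensor(np.ones((2, 4, h, w))),
                     nn.Tensor(rng.normal(size=(2, 1, h, w))))
                 for s, (h, w) in SHAPES.items()}
    targets = [(np.array([[8.0, 8.0, 20.0, 20.0]]), np.array([0])),
               (np.zeros((0, 4)), np.zeros(0, dtype=int))]
    loss = assign_and_loss(level_out, targets, 3)
    assert np.isfinite(loss.data) and loss.data >= 0
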