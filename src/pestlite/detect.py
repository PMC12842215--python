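"""Anchor-free target assignment, detection losses, decoding and NMS.

The head predicts, at strides {4, 8, 16}, per-location class logits,
left/top/right/bottom box distances and a centerness logit.  Ground-truth
boxes are assigned to levels by their max regression distance (0–32 px to
stride 4, 32–64 to stride 8, the rest to stride 16) with center sampling.
The loss is focal classification + complete-IoU box regression + centerness
BCE, normalized by the number of positive locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["Detection", "LEVEL_RANGES", "assign_targets", "assign_and_loss",
           "detection_loss", "nms", "nms_decode", "decode_boxes"]

LEVEL_RANGES = {4: (0.0, 32.0), 8: (32.0, 64.0), 16: (64.0, float("inf"))}
CENTER_RADIUS = 1.5
INF = 1e9


@dataclass
class Detection:
    box: np.ndarray          # xyxy, pixel units, half-open
    class_id: int
    confidence: float
    image_id: int = 0

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(4)
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.box[2] <= self.box[0] or self.box[3] <= self.box[1]:
            raise ValueError("degenerate detection box")


def _grid_centers(h: int, w: int, stride: int) -> np.ndarray:
    ys, xs = np.mgrid[0:h, 0:w]
    return np.stack([(xs + 0.5) * stride, (ys + 0.5) * stride],
                    axis=-1).reshape(-1, 2)


def assign_targets(boxes: np.ndarray, labels: np.ndarray,
                   level_shapes: dict[int, tuple[int, int]],
                   num_classes: int,
                   level_ranges: dict[int, tuple[float, float]] | None = None):
    """Per-level FCOS-style targets.

    Returns {stride: (cls_onehot (N, C), ltrb (N, 4), centerness (N,),
    pos_mask (N,))} with N = H·W locations.
    """
    level_ranges = level_ranges or LEVEL_RANGES
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    labels = np.asarray(labels, dtype=np.int64).reshape(-1)
    out = {}
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]) \
        if len(boxes) else np.zeros(0)
    for stride, (h, w) in level_shapes.items():
        n = h * w
        cls_t = np.zeros((n, num_classes))
        box_t = np.zeros((n, 4))
        ctr_t = np.zeros(n)
        pos = np.zeros(n, dtype=bool)
        if len(boxes):
            cen = _grid_centers(h, w, stride)                    # (n, 2)
            l = cen[:, 0:1] - boxes[None, :, 0]                  # (n, m)
            t = cen[:, 1:2] - boxes[None, :, 1]
            r = boxes[None, :, 2] - cen[:, 0:1]
            b = boxes[None, :, 3] - cen[:, 1:2]
            ltrb = np.stack([l, t, r, b], axis=-1)               # (n, m, 4)
            inside = ltrb.min(axis=-1) > 0
            maxd = ltrb.max(axis=-1)
            lo, hi = level_ranges[stride]
            in_range = (maxd >= lo) & (maxd < hi)
            bc = (boxes[:, :2] + boxes[:, 2:]) / 2.0
            near = (np.abs(cen[:, None, :] - bc[None, :, :]).max(axis=-1)
                    <= CENTER_RADIUS * stride)
            cand = inside & in_range & near
            cost = np.where(cand, areas[None, :], INF)
            best = cost.argmin(axis=1)
            pos = cost.min(axis=1) < INF
            idx = np.nonzero(pos)[0]
            gi = best[idx]
            cls_t[idx, labels[gi]] = 1.0
            box_t[idx] = ltrb[idx, gi]
            lr_min = np.minimum(box_t[idx, 0], box_t[idx, 2])
            lr_max = np.maximum(box_t[idx, 0], box_t[idx, 2])
            tb_min = np.minimum(box_t[idx, 1], box_t[idx, 3])
            tb_max = np.maximum(box_t[idx, 1], box_t[idx, 3])
            ctr_t[idx] = np.sqrt((lr_min / np.maximum(lr_max, 1e-9))
                                 * (tb_min / np.maximum(tb_max, 1e-9)))
        out[stride] = (cls_t, box_t, ctr_t, pos)
    return out


# ---------------------------------------------------------------------------
# Losses (autodiff Tensors)
# ---------------------------------------------------------------------------

def _bce_logits(x: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy with logits."""
    yt = nn.Tensor(y)
    return x.relu() - x * yt + ((-x.abs()).exp() + 1.0).log()


def _focal_loss(logits: Tensor, targets: np.ndarray, alpha: float = 0.25,
                gamma: float = 2.0) -> Tensor:
    p = logits.sigmoid()
    ce = _bce_logits(logits, targets)
    t = nn.Tensor(targets)
    pt = p * t + (1.0 - p) * (1.0 - t)
    alpha_t = alpha * targets + (1 - alpha) * (1 - targets)
    return (ce * (1.0 - pt) ** gamma * nn.Tensor(alpha_t)).sum()


def _ciou_loss(pred_ltrb: Tensor, target_ltrb: np.ndarray,
               centers: np.ndarray) -> Tensor:
    """Complete IoU loss on positive locations (boxes from distances)."""
    cx = nn.Tensor(centers[:, 0])
    cy = nn.Tensor(centers[:, 1])
    px0 = cx - pred_ltrb[:, 0]
    py0 = cy - pred_ltrb[:, 1]
    px1 = cx + pred_ltrb[:, 2]
    py1 = cy + pred_ltrb[:, 3]
    t = target_ltrb
    tx0, ty0 = centers[:, 0] - t[:, 0], centers[:, 1] - t[:, 1]
    tx1, ty1 = centers[:, 0] + t[:, 2], centers[:, 1] + t[:, 3]

    def tmin(a, b):
        return (a + b - (a - b).abs()) * 0.5

    def tmax(a, b):
        return (a + b + (a - b).abs()) * 0.5

    ix0, iy0 = tmax(px0, nn.Tensor(tx0)), tmax(py0, nn.Tensor(ty0))
    ix1, iy1 = tmin(px1, nn.Tensor(tx1)), tmin(py1, nn.Tensor(ty1))
    iw = (ix1 - ix0).clip(0.0, None)
    ih = (iy1 - iy0).clip(0.0, None)
    inter = iw * ih
    p_area = (px1 - px0) * (py1 - py0)
    t_area = (tx1 - tx0) * (ty1 - ty0)
    union = p_area + nn.Tensor(t_area) - inter
    iou = inter / (union + 1e-9)
    # enclosing-box diagonal and center distance
    ex0, ey0 = tmin(px0, nn.Tensor(tx0)), tmin(py0, nn.Tensor(ty0))
    ex1, ey1 = tmax(px1, nn.Tensor(tx1)), tmax(py1, nn.Tensor(ty1))
    diag = (ex1 - ex0) ** 2 + (ey1 - ey0) ** 2 + 1e-9
    pcx, pcy = (px0 + px1) * 0.5, (py0 + py1) * 0.5
    tcx, tcy = (tx0 + tx1) / 2.0, (ty0 + ty1) / 2.0
    dist = (pcx - nn.Tensor(tcx)) ** 2 + (pcy - nn.Tensor(tcy)) ** 2
    # aspect-ratio consistency term
    pw = (px1 - px0).clip(1e-6, None)
    ph = (py1 - py0).clip(1e-6, None)
    tw = np.maximum(tx1 - tx0, 1e-6)
    th = np.maximum(ty1 - ty0, 1e-6)
    v = (4.0 / math.pi ** 2) * ((pw / ph).arctan()
                                - nn.Tensor(np.arctan(tw / th))) ** 2
    with_np = iou.data
    a_coef = v.data / np.maximum(1.0 - with_np + v.data, 1e-9)   # detached
    ciou = iou - dist / diag - nn.Tensor(a_coef) * v
    return (1.0 - ciou).sum()


def detection_loss(level_out: dict, per_image_targets: list[dict],
                   num_classes: int, box_weight: float = 2.0,
                   ctr_weight: float = 1.0) -> tuple[Tensor, dict]:
    """Focal + CIoU + centerness over all levels of a batch.

    ``per_image_targets[b]`` maps stride -> assign_targets output for image b.
    """
    total_pos = sum(t[3].sum() for tgt in per_image_targets for t in tgt.values())
    norm = 1.0 / max(float(total_pos), 1.0)
    cls_loss = nn.Tensor(0.0)
    box_loss = nn.Tensor(0.0)
    ctr_loss = nn.Tensor(0.0)
    for stride, (cls_p, reg_p, ctr_p) in level_out.items():
        B, C = cls_p.shape[0], cls_p.shape[1]
        h, w = cls_p.shape[2], cls_p.shape[3]
        cls_flat = cls_p.reshape(B, C, h * w).transpose(0, 2, 1)
        reg_flat = reg_p.reshape(B, 4, h * w).transpose(0, 2, 1)
        ctr_flat = ctr_p.reshape(B, h * w)
        cls_t = np.stack([tgt[stride][0] for tgt in per_image_targets])
        cls_loss = cls_loss + _focal_loss(cls_flat, cls_t)
        for b, tgt in enumerate(per_image_targets):
            _, box_t, ctr_t, pos = tgt[stride]
            if not pos.any():
                continue
            idx = np.nonzero(pos)[0]
            centers = _grid_centers(h, w, stride)[idx]
            box_loss = box_loss + _ciou_loss(reg_flat[b][idx], box_t[idx],
                                             centers)
            ctr_loss = ctr_loss + _bce_logits(ctr_flat[b][idx],
                                              ctr_t[idx]).sum()
    total = (cls_loss + box_loss * box_weight + ctr_loss * ctr_weight) * norm
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite detection loss")
    parts = {"cls": float(cls_loss.data) * norm,
             "box": float(box_loss.data) * norm,
             "ctr": float(ctr_loss.data) * norm}
    return total, parts


def assign_and_loss(level_out: dict, targets: list[tuple[np.ndarray, np.ndarray]],
                    num_classes: int) -> Tensor:
    """Assign ground truth and compute the loss in one call.

    ``targets`` is a list of (boxes, labels) per image in the batch.
    """
    shapes = {s: (o[0].shape[2], o[0].shape[3]) for s, o in level_out.items()}
    per_image = [assign_targets(b, l, shapes, num_classes) for b, l in targets]
    loss, _ = detection_loss(level_out, per_image, num_classes)
    return loss


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-ordered."""
    from .data import box_iou
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        ious = box_iou(boxes[i][None], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thresh]
    return keep


def decode_boxes(reg: np.ndarray, stride: int) -> np.ndarray:
    """(N, 4) ltrb distances at grid locations -> xyxy boxes."""
    h, w = reg.shape[2], reg.shape[3]
    cen = _grid_centers(h, w, stride)
    d = reg.reshape(4, -1).T
    return np.stack([cen[:, 0] - d[:, 0], cen[:, 1] - d[:, 1],
                     cen[:, 0] + d[:, 2], cen[:, 1] + d[:, 3]], axis=1)


def nms_decode(level_out: dict, conf_thresh: float = 0.25,
               iou_thresh: float = 0.5, image_size: tuple[int, int] | None = None,
               image_id: int = 0, max_dets: int = 100) -> list[Detection]:
    """Decode raw head outputs of one image into NMS-filtered detections."""
    if not 0.0 <= conf_thresh <= 1.0 or not 0.0 <= iou_thresh <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    all_boxes, all_scores, all_cls = [], [], []
    for stride, (cls_p, reg_p, ctr_p) in level_out.items():
        cls = np.asarray(cls_p.data if isinstance(cls_p, Tensor) else cls_p)
        reg = np.asarray(reg_p.data if isinstance(reg_p, Tensor) else reg_p)
        ctr = np.asarray(ctr_p.data if isinstance(ctr_p, Tensor) else ctr_p)
        if cls.ndim == 4:
            cls, reg, ctr = cls[0], reg[0], ctr[0]
        C = cls.shape[0]
        prob = 1 / (1 + np.exp(-cls.reshape(C, -1)))                  # (C, N)
        ctr_prob = 1 / (1 + np.exp(-ctr.reshape(-1)))                 # (N,)
        score = prob * ctr_prob[None, :]
        boxes = decode_boxes(reg[None] if reg.ndim == 3 else reg, stride)
        c_idx, loc_idx = np.nonzero(score >= conf_thresh)
        for c, l in zip(c_idx, loc_idx):
            all_boxes.append(boxes[l])
            all_scores.append(score[c, l])
            all_cls.append(c)
    dets: list[Detection] = []
    if all_boxes:
        boxes = np.array(all_boxes)
        scores = np.array(all_scores)
        classes = np.array(all_cls)
        if image_size is not None:
            h, w = image_size
            boxes[:, 0::2] = boxes[:, 0::2].clip(0, w)
            boxes[:, 1::2] = boxes[:, 1::2].clip(0, h)
        for c in np.unique(classes):
            m = classes == c
            keep = nms(boxes[m], scores[m], iou_thresh)
            bi = np.nonzero(m)[0][keep]
            for i in bi:
                if boxes[i, 2] > boxes[i, 0] and boxes[i, 3] > boxes[i, 1]:
                    dets.append(Detection(boxes[i], int(c), float(scores[i]),
                                          image_id))
    dets.sort(key=lambda d: -d.confidence)
    return dets[:max_dets]
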