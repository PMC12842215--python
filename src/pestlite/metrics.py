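"""Detection and classification metric suite.

Average precision follows the COCO convention: detections are matched to
ground truth greedily in confidence order (one detection per ground-truth
box) at a given IoU cut, and AP integrates the precision envelope at 101
equally spaced recall points.  mAP@50 evaluates at IoU 0.5; mAP@50:95
averages over cuts 0.50:0.05:0.95.  Small-object metrics re-run the same
machinery on the subset of ground truth whose max box dimension is at or
below the small-object threshold (20 px at 640-scale input by default).

"Accuracy" for a detector is computed at image level — an image is flagged
as containing a class when any detection of that class clears the
confidence threshold — which is the only reading under which a true
negative is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import box_iou
from .detect import Detection

__all__ = ["EvalReport", "compute_pr_f1_acc", "match_detections",
           "average_precision", "evaluate_detections", "SMALL_THRESHOLD",
           "IOU_CUTS_50_95"]

SMALL_THRESHOLD = 20.0
IOU_CUTS_50_95 = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    ap_per_class: dict[int, float]
    map50: float
    map50_95: float
    map_small: float | None
    recall_small: float | None
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("precision", "recall", "f1", "accuracy", "map50",
                     "map50_95"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "accuracy": self.accuracy,
                "mAP50": self.map50, "mAP50_95": self.map50_95,
                "mAP_small": self.map_small, "recall_small": self.recall_small,
                "counts": self.counts,
                "AP_per_class": {int(k): v for k, v in self.ap_per_class.items()}}


def compute_pr_f1_acc(tp: int, fp: int, tn: int, fn: int):
    """Exact precision / recall / F1 / accuracy from the four counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as 0",
                          stacklevel=3)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1") \
        if (precision + recall) > 0 else 0.0
    accuracy = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    return precision, recall, f1, accuracy


def match_detections(dets: list[Detection], gt_boxes: np.ndarray,
                     iou_cut: float) -> np.ndarray:
    """Greedy confidence-ordered matching; returns a bool TP flag per
    detection (in the given order), one detection per ground-truth box."""
    matched = np.zeros(len(gt_boxes), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for i, d in enumerate(dets):
        if not len(gt_boxes):
            break
        ious = box_iou(d.box[None], gt_boxes)[0]
        ious[matched] = -1.0
        j = int(ious.argmax())
        if ious[j] >= iou_cut:
            matched[j] = True
            tp[i] = True
    return tp


def average_precision(dets: list[Detection], gts: dict[int, np.ndarray],
                      iou_cut: float = 0.5) -> float:
    """101-point interpolated AP for one class.

    ``dets`` are that class's detections over all images; ``gts`` maps
    image_id -> (M, 4) ground-truth boxes of the class.
    """
    n_gt = sum(len(b) for b in gts.values())
    if n_gt == 0:
        warnings.warn("no ground truth for class; AP undefined", stacklevel=2)
        return float("nan")
    if not dets:
        return 0.0
    dets = sorted(dets, key=lambda d: -d.confidence)
    matched: dict[int, np.ndarray] = {k: np.zeros(len(v), dtype=bool)
                                      for k, v in gts.items()}
    tp = np.zeros(len(dets))
    for i, d in enumerate(dets):
        boxes = gts.get(d.image_id)
        if boxes is None or not len(boxes):
            continue
        ious = box_iou(d.box[None], boxes)[0]
        ious[matched[d.image_id]] = -1.0
        j = int(ious.argmax())
        if ious[j] >= iou_cut:
            matched[d.image_id][j] = True
            tp[i] = 1.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # precision envelope, then 101-point interpolation
    env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, grid, side="left")
    p = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(p.mean())


def _class_gts(images, cls: int, small_only: bool = False,
               small_threshold: float = SMALL_THRESHOLD) -> dict[int, np.ndarray]:
    out = {}
    for img_id, (boxes, labels) in images.items():
        m = labels == cls
        b = boxes[m]
        if small_only and len(b):
            dims = np.maximum(b[:, 2] - b[:, 0], b[:, 3] - b[:, 1])
            b = b[dims <= small_threshold]
        out[img_id] = b
    return out


def evaluate_detections(dets: list[Detection],
                        gt: dict[int, tuple[np.ndarray, np.ndarray]],
                        num_classes: int,
                        conf_thresh: float = 0.25,
                        presence_thresh: float = 0.5,
                        small_threshold: float = SMALL_THRESHOLD) -> EvalReport:
    """Full metric suite over a detection run.

    ``gt`` maps image_id -> (boxes, labels).  Classes with no ground truth
    anywhere are skipped from the mAP means with a warning.
    """
    gt = {k: (np.asarray(b, dtype=float).reshape(-1, 4),
              np.asarray(l, dtype=np.int64).reshape(-1)) for k, (b, l) in gt.items()}
    by_class: dict[int, list[Detection]] = {c: [] for c in range(num_classes)}
    for d in dets:
        if 0 <= d.class_id < num_classes:
            by_class[d.class_id].append(d)

    ap50, ap_all, ap_small = {}, {}, {}
    for c in range(num_classes):
        gts_c = _class_gts(gt, c)
        n_gt = sum(len(v) for v in gts_c.values())
        if n_gt == 0:
            warnings.warn(f"class {c} has no ground truth; skipped",
                          stacklevel=2)
            continue
        ap50[c] = average_precision(by_class[c], gts_c, 0.5)
        ap_all[c] = float(np.mean([average_precision(by_class[c], gts_c, t)
                                   for t in IOU_CUTS_50_95]))
        gts_cs = _class_gts(gt, c, small_only=True,
                            small_threshold=small_threshold)
        if sum(len(v) for v in gts_cs.values()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ap_small[c] = average_precision(by_class[c], gts_cs, 0.5)

    map50 = float(np.mean(list(ap50.values()))) if ap50 else 0.0
    map50_95 = float(np.mean(list(ap_all.values()))) if ap_all else 0.0
    map_small = float(np.mean(list(ap_small.values()))) if ap_small else None

    # detection-level TP/FP/FN at IoU 0.5 above the reporting confidence
    tp = fp = fn = 0
    small_tp = small_n = 0
    for img_id, (boxes, labels) in gt.items():
        for c in range(num_classes):
            dets_c = sorted((d for d in dets if d.image_id == img_id
                             and d.class_id == c and d.confidence >= conf_thresh),
                            key=lambda d: -d.confidence)
            gtb = boxes[labels == c]
            flags = match_detections(dets_c, gtb, 0.5)
            tp += int(flags.sum())
            fp += len(flags) - int(flags.sum())
            fn += len(gtb) - int(flags.sum())
            if len(gtb):
                dims = np.maximum(gtb[:, 2] - gtb[:, 0], gtb[:, 3] - gtb[:, 1])
                small_b = gtb[dims <= small_threshold]
                if len(small_b):
                    small_n += len(small_b)
                    fl = match_detections(dets_c, small_b, 0.5)
                    small_tp += int(fl.sum())
    recall_small = small_tp / small_n if small_n else None

    # image-level presence counts give the TN needed for accuracy
    itp = itn = ifp = ifn = 0
    for img_id, (boxes, labels) in gt.items():
        present = set(labels.tolist())
        flagged = {d.class_id for d in dets
                   if d.image_id == img_id and d.confidence >= presence_thresh}
        for c in range(num_classes):
            if c in present and c in flagged:
                itp += 1
            elif c in present:
                ifn += 1
            elif c in flagged:
                ifp += 1
            else:
                itn += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = compute_pr_f1_acc(tp, fp, 0, fn)
        _, _, _, accuracy = compute_pr_f1_acc(itp, ifp, itn, ifn)
    return EvalReport(precision=precision, recall=recall, f1=f1,
                      accuracy=accuracy, ap_per_class=ap50, map50=map50,
                      map50_95=map50_95, map_small=map_small,
                      recall_small=recall_small,
                      counts={"TP": tp, "FP": fp, "FN": fn,
                              "img_TP": itp, "img_TN": itn,
                              "img_FP": ifp, "img_FN": ifn})
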