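"""Independent brute-force detection evaluator used as a test oracle.

Deliberately naive: for every confidence prefix of the score-sorted
detection list the greedy matching is recomputed from scratch, giving exact
(precision, recall) operating points; AP is then the mean over 101 recall
grid points of the best precision achieved at or beyond that recall.  This
shares no code with the package's vectorized evaluator.
"""

from __future__ import annotations

import numpy as np


def _iou(a, b):
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(ix1 - ix0, 0.0), max(iy1 - iy0, 0.0)
    inter = iw * ih
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def _match_count(dets, gts_by_img, iou_cut):
    """Greedy confidence-ordered matching; returns number of true positives."""
    used = {img: [False] * len(boxes) for img, boxes in gts_by_img.items()}
    tp = 0
    for det in dets:
        img, box, _score = det
        boxes = gts_by_img.get(img, [])
        best, best_iou = -1, iou_cut
        for j, gt in enumerate(boxes):
            if used[img][j]:
                continue
            v = _iou(box, gt)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            used[img][best] = True
            tp += 1
    return tp


def oracle_ap(dets, gts_by_img, iou_cut):
    """dets: list of (image_id, box, score); gts_by_img: image_id -> [boxes]."""
    n_gt = sum(len(v) for v in gts_by_img.values())
    if n_gt == 0:
        return float("nan")
    if not dets:
        return 0.0
    dets = sorted(dets, key=lambda d: -d[2])
    points = []          # (recall, precision) for every prefix
    for k in range(1, len(dets) + 1):
        tp = _match_count(dets[:k], gts_by_img, iou_cut)
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for rec, prec in points:
            if rec >= r - 1e-12 and prec > best:
                best = prec
        ap += best
    return ap / 101.0


def oracle_map(dets_by_class, gts_by_class, iou_cuts):
    """Mean over classes and IoU cuts of the brute-force AP."""
    vals = []
    for c, gts in gts_by_class.items():
        if sum(len(v) for v in gts.values()) == 0:
            continue
        per_cut = [oracle_ap(dets_by_class.get(c, []), gts, t)
                   for t in iou_cuts]
        vals.append(np.mean(per_cut))
    return float(np.mean(vals)) if vals else 0.0
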