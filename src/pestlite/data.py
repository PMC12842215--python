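"""Annotated-image container and COCO-style dataset I/O.

``AnnotatedImage`` is the universal record flowing through augmentation,
training and evaluation: float pixels in [0, 1] (H, W, 3), half-open pixel
boxes (x_min, y_min, x_max, y_max) and integer class labels.  Datasets are
exchanged as a directory of PNGs plus a COCO detection JSON
(``annotations.json`` with images / annotations / categories; bbox stored
as [x, y, w, h]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["AnnotatedImage", "write_coco", "read_coco", "box_area", "box_iou"]


@dataclass
class AnnotatedImage:
    pixels: np.ndarray                       # (H, W, 3) float64 in [0, 1]
    boxes: np.ndarray                        # (N, 4) xyxy, half-open
    labels: np.ndarray                       # (N,) int
    weights: np.ndarray | None = None        # per-box mixing weight
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.weights is None:
            self.weights = np.ones(len(self.boxes))
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if len(self.boxes) != len(self.labels) or len(self.boxes) != len(self.weights):
            raise ValueError("boxes, labels and weights must align")

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def validate(self, n_classes: int | None = None):
        h, w = self.size
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        b = self.boxes
        if len(b):
            if (b[:, 0] < -1e-9).any() or (b[:, 1] < -1e-9).any() \
                    or (b[:, 2] > w + 1e-9).any() or (b[:, 3] > h + 1e-9).any():
                raise ValueError("box outside image bounds")
            if (b[:, 2] <= b[:, 0]).any() or (b[:, 3] <= b[:, 1]).any():
                raise ValueError("degenerate box (non-positive extent)")
        if n_classes is not None and len(self.labels) \
                and (self.labels.min() < 0 or self.labels.max() >= n_classes):
            raise ValueError("label outside class range")
        return self

    def copy(self) -> "AnnotatedImage":
        return AnnotatedImage(self.pixels.copy(), self.boxes.copy(),
                              self.labels.copy(), self.weights.copy(),
                              dict(self.meta))


def box_area(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    return np.maximum(boxes[:, 2] - boxes[:, 0], 0) * \
        np.maximum(boxes[:, 3] - boxes[:, 1], 0)


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) xyxy boxes -> (N, M)."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.maximum(rb - lt, 0)
    inter = wh[..., 0] * wh[..., 1]
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def write_coco(images: list[AnnotatedImage], out_dir, class_names: list[str],
               save_pixels: bool = True) -> Path:
    """Write PNGs + a COCO detection JSON; returns the JSON path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    recs, anns = [], []
    ann_id = 1
    for i, img in enumerate(images):
        h, w = img.size
        fname = f"{i:06d}.png"
        if save_pixels:
            arr = np.clip(img.pixels * 255.0, 0, 255).round().astype(np.uint8)
            Image.fromarray(arr).save(out_dir / "images" / fname)
        recs.append({"id": i + 1, "file_name": fname, "height": h, "width": w,
                     **({"split": img.meta["split"]} if "split" in img.meta else {})})
        for box, lab, wt in zip(img.boxes, img.labels, img.weights):
            x0, y0, x1, y1 = (float(v) for v in box)
            anns.append({"id": ann_id, "image_id": i + 1,
                         "category_id": int(lab) + 1,
                         "bbox": [x0, y0, x1 - x0, y1 - y0],
                         "area": (x1 - x0) * (y1 - y0),
                         "iscrowd": 0, "weight": float(wt)})
            ann_id += 1
    doc = {"images": recs,
           "annotations": anns,
           "categories": [{"id": c + 1, "name": n}
                          for c, n in enumerate(class_names)]}
    path = out_dir / "annotations.json"
    path.write_text(json.dumps(doc))
    return path


def read_coco(json_path, images_dir=None) -> tuple[list[AnnotatedImage], list[str]]:
    """Load a COCO detection JSON back into annotated images."""
    json_path = Path(json_path)
    doc = json.loads(json_path.read_text())
    images_dir = Path(images_dir) if images_dir else json_path.parent / "images"
    by_img: dict[int, list[dict]] = {}
    for a in doc["annotations"]:
        by_img.setdefault(a["image_id"], []).append(a)
    cats = sorted(doc["categories"], key=lambda c: c["id"])
    names = [c["name"] for c in cats]
    cat_to_label = {c["id"]: i for i, c in enumerate(cats)}
    out = []
    for rec in doc["images"]:
        p = images_dir / rec["file_name"]
        if p.exists():
            pixels = np.asarray(Image.open(p), dtype=np.float64) / 255.0
        else:
            pixels = np.zeros((rec["height"], rec["width"], 3))
        anns = by_img.get(rec["id"], [])
        boxes = np.array([[a["bbox"][0], a["bbox"][1],
                           a["bbox"][0] + a["bbox"][2],
                           a["bbox"][1] + a["bbox"][3]] for a in anns]
                         ).reshape(-1, 4)
        labels = np.array([cat_to_label[a["category_id"]] for a in anns],
                          dtype=np.int64)
        weights = np.array([a.get("weight", 1.0) for a in anns])
        meta = {"source": rec["file_name"]}
        if "split" in rec:
            meta["split"] = rec["split"]
        out.append(AnnotatedImage(pixels, boxes, labels, weights, meta))
    return out, names
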