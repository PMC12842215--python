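"""Box-aware augmentation suite for greenhouse imagery.

Operators: color jitter (brightness/contrast/saturation/hue), occlusion
cutout, crop–resize (the main scale amplifier for 5–20 px pests), four-image
mosaic, convex mixup, and small-object copy–paste.  Every operator keeps the
annotations consistent — boxes are remapped, clipped, or dropped with the
image — and is bit-reproducible from a seeded generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import AnnotatedImage, box_area, box_iou

__all__ = ["AugmentConfig", "color_jitter", "cutout", "crop_resize", "mosaic",
           "mixup", "copy_paste_small", "extract_small_objects", "Augmenter"]

SMALL_OBJECT_PX = 20.0   # max box dimension of a "small" pest at 640 input


@dataclass
class AugmentConfig:
    brightness: tuple[float, float] = (0.7, 1.3)     # α
    contrast: tuple[float, float] = (0.7, 1.3)       # β
    saturation: tuple[float, float] = (0.7, 1.3)     # γ
    hue: tuple[float, float] = (-0.08, 0.08)         # δ, fraction of a turn
    cutout_count: tuple[int, int] = (1, 3)
    cutout_size: tuple[float, float] = (0.05, 0.2)   # fraction of min(H, W)
    cutout_drop_coverage: float = 0.9
    crop_scale: tuple[float, float] = (0.5, 1.0)
    crop_min_box_survival: float = 0.25
    mixup_beta: float = 1.0                          # λ ~ Beta(α, α)
    copy_paste_n: tuple[int, int] = (1, 5)
    copy_paste_scale: tuple[float, float] = (0.8, 1.25)
    max_paste_iou: float = 0.2
    small_threshold: float = SMALL_OBJECT_PX
    p_color: float = 0.8
    p_cutout: float = 0.3
    p_crop: float = 0.5
    p_mosaic: float = 0.3
    p_mixup: float = 0.15
    p_copy_paste: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("brightness", "contrast", "saturation", "hue",
                     "cutout_size", "crop_scale", "copy_paste_scale"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must be non-degenerate")
        for name in ("p_color", "p_cutout", "p_crop", "p_mosaic", "p_mixup",
                     "p_copy_paste"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


# YIQ hue-rotation matrix machinery: rotating the chroma plane shifts hue
# while the neutral angle (δ=0) is the exact identity.
_RGB2YIQ = np.array([[0.299, 0.587, 0.114],
                     [0.596, -0.274, -0.322],
                     [0.211, -0.523, 0.312]])
_YIQ2RGB = np.linalg.inv(_RGB2YIQ)


def color_jitter(img: AnnotatedImage, alpha: float = 1.0, beta: float = 1.0,
                 gamma: float = 1.0, delta: float = 0.0) -> AnnotatedImage:
    """Photometric transform: geometry and boxes are untouched.

    ``alpha`` scales brightness, ``beta`` contrast (about the image mean),
    ``gamma`` saturation (blend with per-pixel luma), ``delta`` rotates hue
    (in turns).  Neutral parameters return the input bit-identically.
    """
    out = img.copy()
    x = out.pixels
    if delta != 0.0:
        ang = 2.0 * np.pi * delta
        rot = np.array([[1, 0, 0],
                        [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        x = x @ (_RGB2YIQ.T @ rot.T @ _YIQ2RGB.T)
    if gamma != 1.0:
        luma = x @ np.array([0.299, 0.587, 0.114])
        x = luma[..., None] + gamma * (x - luma[..., None])
    if beta != 1.0:
        m = x.mean()
        x = m + beta * (x - m)
    if alpha != 1.0:
        x = alpha * x
    if not (alpha == 1.0 and beta == 1.0 and gamma == 1.0 and delta == 0.0):
        x = np.clip(x, 0.0, 1.0)
    out.pixels = x
    return out


def cutout(img: AnnotatedImage, mask: np.ndarray,
           fill: float | str = 0.0, rng: np.random.Generator | None = None,
           drop_coverage: float = 0.9) -> AnnotatedImage:
    """Occlude the masked region; boxes almost fully covered are dropped."""
    mask = np.asarray(mask)
    h, w = img.size
    if mask.shape != (h, w):
        raise ValueError(f"mask shape {mask.shape} does not match image {h}x{w}")
    m = mask.astype(bool)
    out = img.copy()
    if fill == "noise":
        rng = rng or np.random.default_rng(0)
        out.pixels[m] = rng.uniform(0, 1, size=(int(m.sum()), 3))
    else:
        out.pixels[m] = float(fill)
    keep = []
    for i, b in enumerate(out.boxes):
        x0, y0, x1, y1 = (int(np.floor(b[0])), int(np.floor(b[1])),
                          int(np.ceil(b[2])), int(np.ceil(b[3])))
        region = m[max(y0, 0):y1, max(x0, 0):x1]
        cov = region.mean() if region.size else 1.0
        if cov <= drop_coverage:
            keep.append(i)
    out.boxes = out.boxes[keep]
    out.labels = out.labels[keep]
    out.weights = out.weights[keep]
    return out


def _resize(pixels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = pixels.shape[:2]
    if (h, w) == (out_h, out_w):
        return pixels.copy()
    zoom = (out_h / h, out_w / w, 1.0)
    return np.clip(ndimage.zoom(pixels, zoom, order=1, grid_mode=True,
                                mode="nearest"), 0.0, 1.0)


def crop_resize(img: AnnotatedImage, window: tuple[float, float, float, float],
                out_size: tuple[int, int],
                min_survival: float = 0.25) -> AnnotatedImage:
    """Crop ``window`` (x0, y0, x1, y1) and resize to ``out_size`` (H, W).

    Boxes are offset, rescaled and clipped; a box keeping less than
    ``min_survival`` of its area is dropped.
    """
    h, w = img.size
    x0, y0, x1, y1 = window
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"window {window} outside image {w}x{h}")
    out_h, out_w = out_size
    ix0, iy0, ix1, iy1 = int(round(x0)), int(round(y0)), int(round(x1)), int(round(y1))
    crop = img.pixels[iy0:iy1, ix0:ix1]
    pixels = _resize(crop, out_h, out_w)
    sx, sy = out_w / (ix1 - ix0), out_h / (iy1 - iy0)
    boxes, labels, weights = [], [], []
    for b, lab, wt in zip(img.boxes, img.labels, img.weights):
        nb = np.array([(b[0] - ix0) * sx, (b[1] - iy0) * sy,
                       (b[2] - ix0) * sx, (b[3] - iy0) * sy])
        clipped = np.array([max(nb[0], 0), max(nb[1], 0),
                            min(nb[2], out_w), min(nb[3], out_h)])
        full = box_area(nb[None])[0]
        surv = box_area(clipped[None])[0]
        if full > 0 and surv / full >= min_survival:
            boxes.append(clipped)
            labels.append(lab)
            weights.append(wt)
    return AnnotatedImage(pixels, np.array(boxes).reshape(-1, 4),
                          np.array(labels, dtype=np.int64), np.array(weights),
                          dict(img.meta))


def mosaic(imgs: list[AnnotatedImage], canvas_size: tuple[int, int],
           center: tuple[float, float] | None = None,
           rng: np.random.Generator | None = None,
           min_survival: float = 0.25) -> AnnotatedImage:
    """Four-image mosaic: sources resized to the target size are anchored
    around a center point on a double-size canvas, which is then cropped to
    ``canvas_size`` about that center."""
    if len(imgs) != 4:
        raise ValueError("mosaic needs exactly 4 images")
    H, W = canvas_size
    if center is None:
        rng = rng or np.random.default_rng(0)
        center = (W + rng.uniform(-0.5, 0.5) * W, H + rng.uniform(-0.5, 0.5) * H)
    cx, cy = center
    if not (W * 0.5 <= cx <= W * 1.5 and H * 0.5 <= cy <= H * 1.5):
        raise ValueError("mosaic center must lie in the central 50% region")
    canvas = np.zeros((2 * H, 2 * W, 3))
    boxes, labels, weights = [], [], []
    anchors = [(cx - W, cy - H), (cx, cy - H), (cx - W, cy), (cx, cy)]
    for img, (ax, ay) in zip(imgs, anchors):
        pix = _resize(img.pixels, H, W)
        iax, iay = int(round(ax)), int(round(ay))
        dx0, dy0 = max(iax, 0), max(iay, 0)
        dx1, dy1 = min(iax + W, 2 * W), min(iay + H, 2 * H)
        if dx1 > dx0 and dy1 > dy0:
            canvas[dy0:dy1, dx0:dx1] = pix[dy0 - iay:dy1 - iay,
                                           dx0 - iax:dx1 - iax]
        sy, sx = H / img.size[0], W / img.size[1]
        for b, lab, wt in zip(img.boxes, img.labels, img.weights):
            boxes.append([b[0] * sx + iax, b[1] * sy + iay,
                          b[2] * sx + iax, b[3] * sy + iay])
            labels.append(lab)
            weights.append(wt)
    out = AnnotatedImage(canvas, np.array(boxes).reshape(-1, 4),
                         np.array(labels, dtype=np.int64), np.array(weights),
                         dict(imgs[0].meta))
    x0, y0 = int(round(cx - W / 2)), int(round(cy - H / 2))
    return crop_resize(out, (x0, y0, x0 + W, y0 + H), (H, W),
                       min_survival=min_survival)


def mixup(img_a: AnnotatedImage, img_b: AnnotatedImage,
          lam: float) -> AnnotatedImage:
    """Convex pixel blend; the annotation set is the union of both inputs,
    with per-box weights recording the mixing coefficient."""
    if img_a.size != img_b.size:
        raise ValueError("mixup inputs must share the same size")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("λ must lie in [0, 1]")
    pixels = lam * img_a.pixels + (1.0 - lam) * img_b.pixels
    boxes = np.concatenate([img_a.boxes, img_b.boxes])
    labels = np.concatenate([img_a.labels, img_b.labels])
    weights = np.concatenate([img_a.weights * lam, img_b.weights * (1.0 - lam)])
    return AnnotatedImage(pixels, boxes, labels, weights, dict(img_a.meta))


def extract_small_objects(imgs: list[AnnotatedImage],
                          threshold: float = SMALL_OBJECT_PX
                          ) -> list[tuple[np.ndarray, int]]:
    """Collect (patch, label) donor crops whose max dimension ≤ threshold."""
    donors = []
    for img in imgs:
        for b, lab in zip(img.boxes, img.labels):
            w, h = b[2] - b[0], b[3] - b[1]
            if max(w, h) <= threshold and min(w, h) >= 2:
                x0, y0 = int(np.floor(b[0])), int(np.floor(b[1]))
                x1, y1 = int(np.ceil(b[2])), int(np.ceil(b[3]))
                patch = img.pixels[y0:y1, x0:x1]
                if patch.size:
                    donors.append((patch.copy(), int(lab)))
    return donors


def copy_paste_small(img: AnnotatedImage, donors: list[tuple[np.ndarray, int]],
                     config: AugmentConfig,
                     rng: np.random.Generator) -> AnnotatedImage:
    """Paste N scaled small-object crops at random positions.

    A paste succeeds only when its box overlaps every existing and
    previously pasted box with IoU ≤ ``config.max_paste_iou``; edge pixels
    are feathered into the background.
    """
    n = int(rng.integers(config.copy_paste_n[0], config.copy_paste_n[1] + 1))
    if n == 0:
        return img.copy()
    if not donors:
        warnings.warn("copy-paste requested but donor pool is empty", stacklevel=2)
        return img.copy()
    out = img.copy()
    h, w = out.size
    new_boxes, new_labels = [], []
    for _ in range(n):
        patch, lab = donors[int(rng.integers(len(donors)))]
        lam = rng.uniform(*config.copy_paste_scale)
        ph = max(2, int(round(patch.shape[0] * lam)))
        pw = max(2, int(round(patch.shape[1] * lam)))
        if ph >= h or pw >= w:
            continue
        scaled = _resize(patch, ph, pw)
        x0 = int(rng.integers(0, w - pw))
        y0 = int(rng.integers(0, h - ph))
        cand = np.array([x0, y0, x0 + pw, y0 + ph], dtype=float)
        existing = np.concatenate([out.boxes, np.array(new_boxes).reshape(-1, 4)])
        if len(existing) and box_iou(cand[None], existing).max() > config.max_paste_iou:
            continue
        mask = np.ones((ph, pw))
        if ph > 2 and pw > 2:   # 1-px feathered edge
            mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = 0.5
        region = out.pixels[y0:y0 + ph, x0:x0 + pw]
        out.pixels[y0:y0 + ph, x0:x0 + pw] = \
            mask[..., None] * scaled + (1 - mask[..., None]) * region
        new_boxes.append(cand)
        new_labels.append(lab)
    if new_boxes:
        out.boxes = np.concatenate([out.boxes, np.array(new_boxes)])
        out.labels = np.concatenate([out.labels,
                                     np.array(new_labels, dtype=np.int64)])
        out.weights = np.concatenate([out.weights, np.ones(len(new_boxes))])
    return out


class Augmenter:
    """Seeded stochastic pipeline applying the full suite with the
    configured per-operator probabilities."""

    def __init__(self, config: AugmentConfig | None = None,
                 donor_pool: list | None = None):
        self.config = config or AugmentConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.donor_pool = donor_pool or []

    def __call__(self, img: AnnotatedImage,
                 pool: list[AnnotatedImage] | None = None) -> AnnotatedImage:
        cfg, rng = self.config, self.rng
        out = img
        if pool and len(pool) >= 4 and rng.random() < cfg.p_mosaic:
            picks = [pool[int(rng.integers(len(pool)))] for _ in range(3)]
            out = mosaic([out] + picks, out.size, rng=rng)
        if pool and rng.random() < cfg.p_mixup:
            other = pool[int(rng.integers(len(pool)))]
            if other.size == out.size:
                lam = float(rng.beta(cfg.mixup_beta, cfg.mixup_beta))
                out = mixup(out, other, lam)
        if rng.random() < cfg.p_crop:
            h, w = out.size
            s = rng.uniform(*cfg.crop_scale)
            cw, ch = max(8, int(w * s)), max(8, int(h * s))
            x0 = int(rng.integers(0, w - cw + 1))
            y0 = int(rng.integers(0, h - ch + 1))
            out = crop_resize(out, (x0, y0, x0 + cw, y0 + ch), (h, w),
                              min_survival=cfg.crop_min_box_survival)
        if rng.random() < cfg.p_color:
            out = color_jitter(out,
                               alpha=rng.uniform(*cfg.brightness),
                               beta=rng.uniform(*cfg.contrast),
                               gamma=rng.uniform(*cfg.saturation),
                               delta=rng.uniform(*cfg.hue))
        if rng.random() < cfg.p_cutout:
            h, w = out.size
            m = np.zeros((h, w))
            for _ in range(int(rng.integers(cfg.cutout_count[0],
                                            cfg.cutout_count[1] + 1))):
                sz = rng.uniform(*cfg.cutout_size) * min(h, w)
                sz = max(1, int(sz))
                x0 = int(rng.integers(0, max(w - sz, 1)))
                y0 = int(rng.integers(0, max(h - sz, 1)))
                m[y0:y0 + sz, x0:x0 + sz] = 1
            out = cutout(out, m, drop_coverage=cfg.cutout_drop_coverage)
        if self.donor_pool and rng.random() < cfg.p_copy_paste:
            out = copy_paste_small(out, self.donor_pool, cfg, rng)
        return out
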