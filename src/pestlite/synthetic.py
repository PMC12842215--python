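"""Seeded synthetic greenhouse scenes with COCO annotations.

Statistical stand-in for a real greenhouse pest/disease dataset: cluttered
leaf-texture backgrounds under a low-frequency illumination field, specular
highlight streaks and local vapor-blur patches, and three object classes —
two micro-pest classes whose max box dimension is log-uniform on [5, 20] px
(dark beetle-like and bright whitefly-like bodies) and a lesion class at
log-uniform [20, 80] px.  Visual realism is a non-goal; the contract is the
statistical structure: scale marginals, clutter, contrast, class imbalance,
and bit-reproducibility per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import AnnotatedImage, box_iou, write_coco

__all__ = ["SceneSpec", "generate_scene", "generate_dataset", "sample_size",
           "CLASS_NAMES"]

CLASS_NAMES = ["beetle", "whitefly", "lesion"]


@dataclass
class SceneSpec:
    canvas_size: tuple[int, int] = (640, 640)
    n_classes: int = 3
    object_rate: float = 5.0                  # objects per image ~ Poisson
    pest_size: tuple[float, float] = (5.0, 20.0)     # log-uniform, px
    lesion_size: tuple[float, float] = (20.0, 80.0)  # log-uniform, px
    class_weights: tuple[float, ...] = (0.45, 0.30, 0.25)
    clutter: int = 25                         # background leaf count
    illumination: float = 0.25                # low-frequency field amplitude
    specular_prob: float = 0.5
    vapor_prob: float = 0.3
    max_overlap_iou: float = 0.3

    def __post_init__(self):
        if len(self.class_weights) != self.n_classes:
            raise ValueError("class_weights must have one entry per class")
        for p in (self.specular_prob, self.vapor_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1")

    @classmethod
    def _preset(cls, defaults: dict, kw: dict) -> "SceneSpec":
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def easy(cls, **kw) -> "SceneSpec":
        return cls._preset(dict(specular_prob=0.0, vapor_prob=0.0, clutter=10,
                                illumination=0.1), kw)

    @classmethod
    def hard(cls, **kw) -> "SceneSpec":
        return cls._preset(dict(specular_prob=0.9, vapor_prob=0.7, clutter=40,
                                illumination=0.4), kw)

    @classmethod
    def benchmark(cls, canvas: int = 320, **kw) -> "SceneSpec":
        """Desk-scale benchmark preset used by the ablation runner."""
        return cls._preset(dict(canvas_size=(canvas, canvas), object_rate=4.0,
                                clutter=max(6, canvas // 16), specular_prob=0.3,
                                vapor_prob=0.2), kw)


def sample_size(class_id: int, spec: SceneSpec,
                rng: np.random.Generator) -> float:
    """Draw a max-box-dimension: log-uniform on the class's size range."""
    lo, hi = spec.lesion_size if class_id == 2 else spec.pest_size
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.canvas_size
    img = np.empty((h, w, 3))
    base = np.array([0.18, 0.42, 0.16]) + rng.uniform(-0.03, 0.03, 3)
    img[:] = base
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.clutter):            # overlapping leaf ellipses
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        a, b = rng.uniform(0.08, 0.35, 2) * min(h, w)
        th = rng.uniform(0, np.pi)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        tint = np.array([rng.uniform(-0.05, 0.05),
                         rng.uniform(-0.10, 0.15),
                         rng.uniform(-0.05, 0.05)])
        img[mask] = np.clip(img[mask] + tint, 0, 1)
    # vein-like texture noise
    img += rng.normal(0, 0.015, size=(h, w, 1))
    # low-frequency illumination field
    coarse = rng.normal(0, 1.0, size=(4, 4))
    field = ndimage.zoom(coarse, (h / 4, w / 4), order=3)[:h, :w]
    field = spec.illumination * field / max(np.abs(field).max(), 1e-9)
    img *= (1.0 + field)[..., None]
    return np.clip(img, 0, 1)


def _ellipse_axes(size: float, ecc: float, theta: float):
    """Semi-axes so the rotated ellipse's bbox max dimension equals size."""
    a, b = size / 2.0, size * ecc / 2.0
    ex = np.hypot(a * np.cos(theta), b * np.sin(theta))
    ey = np.hypot(a * np.sin(theta), b * np.cos(theta))
    s = (size / 2.0) / max(ex, ey)
    return a * s, b * s


def _render_object(img: np.ndarray, cls: int, size: float, cx: float, cy: float,
                   rng: np.random.Generator) -> tuple[float, float, float, float] | None:
    h, w = img.shape[:2]
    r = int(np.ceil(size / 2)) + 2
    x0, x1 = int(cx) - r, int(cx) + r + 1
    y0, y1 = int(cy) - r, int(cy) + r + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    theta = rng.uniform(0, np.pi)
    if cls == 2:                     # lesion: irregular multi-lobe blob
        mask = np.zeros(yy.shape, dtype=bool)
        lobes = rng.integers(2, 5)
        for _ in range(lobes):
            ox, oy = rng.uniform(-0.15, 0.15, 2) * size
            th = rng.uniform(0, np.pi)
            a, b = _ellipse_axes(size * rng.uniform(0.6, 0.95),
                                 rng.uniform(0.5, 0.9), th)
            dx, dy = xx - (cx + ox), yy - (cy + oy)
            u = dx * np.cos(th) + dy * np.sin(th)
            v = -dx * np.sin(th) + dy * np.cos(th)
            mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        color = np.array([0.45, 0.30, 0.10]) + rng.uniform(-0.08, 0.08, 3)
        blend = 0.85
    else:
        ecc = rng.uniform(0.55, 0.9)
        a, b = _ellipse_axes(size, ecc, theta)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if cls == 0:                 # beetle: dark textured body
            color = np.array([0.08, 0.06, 0.04]) + rng.uniform(0, 0.04, 3)
        else:                        # whitefly: bright speck
            color = np.array([0.92, 0.92, 0.85]) + rng.uniform(-0.05, 0.05, 3)
        blend = 1.0
    if not mask.any():
        return None
    patch = img[y0:y1, x0:x1]
    texture = rng.normal(0, 0.03, size=mask.sum())[:, None]
    patch[mask] = np.clip((1 - blend) * patch[mask]
                          + blend * (color + texture), 0, 1)
    ys, xs = np.nonzero(mask)
    return (x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1.0, y0 + ys.max() + 1.0)


def _nuisance(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator):
    h, w = img.shape[:2]
    if rng.random() < spec.specular_prob:    # bright reflective streak
        for _ in range(rng.integers(1, 3)):
            x = np.linspace(rng.uniform(0, w), rng.uniform(0, w), 200)
            y = np.linspace(rng.uniform(0, h), rng.uniform(0, h), 200)
            streak = np.zeros((h, w))
            xi = np.clip(x.astype(int), 0, w - 1)
            yi = np.clip(y.astype(int), 0, h - 1)
            streak[yi, xi] = 1.0
            streak = ndimage.gaussian_filter(streak, rng.uniform(1.5, 4.0))
            streak /= max(streak.max(), 1e-9)
            img += 0.55 * streak[..., None]
    if rng.random() < spec.vapor_prob:       # local blur patch
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        rad = rng.uniform(0.15, 0.35) * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        weight = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * rad ** 2)))
        blurred = ndimage.gaussian_filter(img, (3.0, 3.0, 0))
        img[:] = weight[..., None] * blurred + (1 - weight[..., None]) * img
    np.clip(img, 0, 1, out=img)


def generate_scene(spec: SceneSpec, rng: np.random.Generator) -> AnnotatedImage:
    """Render one annotated scene; every object carries a tight box."""
    img = _background(spec, rng)
    h, w = spec.canvas_size
    n = int(rng.poisson(spec.object_rate))
    boxes, labels = [], []
    for _ in range(n):
        cls = int(rng.choice(spec.n_classes, p=spec.class_weights))
        size = sample_size(cls, spec, rng)
        size = min(size, 0.45 * min(h, w))   # keep objects inside small canvases
        for _try in range(12):
            cx = rng.uniform(size, w - size)
            cy = rng.uniform(size, h - size)
            cand = np.array([cx - size / 2, cy - size / 2,
                             cx + size / 2, cy + size / 2])
            if boxes and box_iou(cand[None], np.array(boxes)).max() \
                    > spec.max_overlap_iou:
                continue
            bb = _render_object(img, cls, size, cx, cy, rng)
            if bb is not None:
                boxes.append(list(bb))
                labels.append(cls)
            break
    _nuisance(img, spec, rng)
    return AnnotatedImage(img, np.array(boxes).reshape(-1, 4),
                          np.array(labels, dtype=np.int64)).validate(spec.n_classes)


def generate_dataset(spec: SceneSpec, n_images: int, out_dir=None,
                     seed: int = 0) -> list[AnnotatedImage] | Path:
    """Generate ``n_images`` scenes; if ``out_dir`` is given, write a COCO
    dataset (PNGs + annotations.json) and return the JSON path."""
    rng = np.random.default_rng(seed)
    images = [generate_scene(spec, rng) for _ in range(n_images)]
    if out_dir is None:
        return images
    return write_coco(images, out_dir, CLASS_NAMES[: spec.n_classes])
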