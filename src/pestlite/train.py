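"""Training loop, stratified splitting and cross-validation.

Defaults follow the experimental protocol: stratified 7:2:1 split, batch
size 32, AdamW at initial learning rate 1e-3 with cosine annealing, and
optional 5-fold cross-validation.  One master seed fans out to independent
streams for splitting, augmentation, weight init and batch order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augment import Augmenter, AugmentConfig, extract_small_objects
from .blsd import (DistillState, distill_losses, forward_student_with_substitution,
                   schedule_alpha, _descriptor_tokens)
from .data import AnnotatedImage
from .detect import assign_targets, detection_loss, nms_decode, _bce_logits
from .metrics import EvalReport, evaluate_detections
from .model import DetectionModel

__all__ = ["TrainConfig", "TrainingDiverged", "stratified_split",
           "kfold_splits", "Trainer", "evaluate_model", "train"]


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 0.01
    epochs: int = 24
    schedule: str = "cosine"
    optimizer: str = "adamw"
    split_ratio: tuple[float, float, float] = (0.7, 0.2, 0.1)
    folds: int | None = None
    seed: int = 0
    box_weight: float = 2.0
    ctr_weight: float = 1.0
    img_cls_weight: float = 0.2
    distill_weight: float = 0.1
    warmup_epochs: int = 2
    clip_norm: float = 5.0         # global gradient-norm clip (0 disables)
    augment: AugmentConfig | None = None
    divergence_threshold: float = 1e4
    eval_every: int = 0            # 0 = only at the end

    def __post_init__(self):
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.folds is not None and self.folds < 2:
            raise ValueError("folds must be >= 2 when set")
        if self.schedule not in ("cosine", "constant"):
            raise ValueError("schedule must be 'cosine' or 'constant'")


def _strat_key(img: AnnotatedImage, class_freq: dict[int, int] | None = None) -> int:
    """Stratum of a multi-label image: its globally rarest present class
    (so minority classes get their own stratum), or -1 when empty."""
    if not len(img.labels):
        return -1
    present = np.unique(img.labels)
    if class_freq is None:
        vals, counts = np.unique(img.labels, return_counts=True)
        return int(vals[counts.argmax()])
    return int(min(present, key=lambda c: (class_freq.get(int(c), 0), c)))


def stratified_split(images: list[AnnotatedImage],
                     ratio: tuple[float, float, float] = (0.7, 0.2, 0.1),
                     seed: int = 0):
    """Class-stratified train/val/test partition.

    Each image is stratified by its rarest present class; per-stratum
    counts in every split land within ±1 of the exact proportional
    allocation (largest-remainder rounding).  Raises when a class is
    present in fewer than 3 images.
    """
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError("ratio must sum to 1")
    rng = np.random.default_rng(seed)
    presence: dict[int, int] = {}
    for img in images:
        for c in np.unique(img.labels):
            presence[int(c)] = presence.get(int(c), 0) + 1
    thin = sorted(c for c, n in presence.items() if n < 3)
    if thin:
        raise ValueError(f"classes with fewer than 3 images: {thin}")
    keys = np.array([_strat_key(img, presence) for img in images])
    splits: tuple[list, list, list] = ([], [], [])
    for c in np.unique(keys):
        idx = np.nonzero(keys == c)[0]
        rng.shuffle(idx)
        n = len(idx)
        exact = np.array(ratio) * n
        counts = np.floor(exact).astype(int)
        rem = np.argsort(-(exact - counts), kind="stable")
        for k in rem[: n - counts.sum()]:
            counts[k] += 1
        off = 0
        for s, cnt in enumerate(counts):
            splits[s].extend(int(i) for i in idx[off:off + cnt])
            off += cnt
    train_i, val_i, test_i = (sorted(s) for s in splits)
    return ([images[i] for i in train_i], [images[i] for i in val_i],
            [images[i] for i in test_i])


def kfold_splits(images: list[AnnotatedImage], folds: int = 5, seed: int = 0):
    """Stratified k-fold assignment; every image validates exactly once."""
    presence: dict[int, int] = {}
    for img in images:
        for c in np.unique(img.labels):
            presence[int(c)] = presence.get(int(c), 0) + 1
    keys = np.array([_strat_key(img, presence) for img in images])
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(len(images), dtype=int)
    for c in np.unique(keys):
        idx = np.nonzero(keys == c)[0]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[i] = j % folds
    for f in range(folds):
        tr = [img for img, g in zip(images, fold_of) if g != f]
        va = [img for img, g in zip(images, fold_of) if g == f]
        yield tr, va


def _batch_tensor(images: list[AnnotatedImage]) -> np.ndarray:
    return np.stack([img.pixels.transpose(2, 0, 1) for img in images])


def evaluate_model(model: DetectionModel, images: list[AnnotatedImage],
                   conf_thresh: float = 0.05, small_threshold: float = 20.0,
                   batch: int = 8) -> EvalReport:
    """Run inference and score the full metric suite."""
    model.eval()
    dets, gt = [], {}
    with nn.no_grad():
        for start in range(0, len(images), batch):
            chunk = images[start:start + batch]
            out, _ = model(_batch_tensor(chunk))
            for b, img in enumerate(chunk):
                img_id = start + b
                lv = {s: (c.data[b:b + 1], r.data[b:b + 1], t.data[b:b + 1])
                      for s, (c, r, t) in out.items()}
                dets.extend(nms_decode(lv, conf_thresh=conf_thresh,
                                       image_size=img.size, image_id=img_id))
                gt[img_id] = (img.boxes, img.labels)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_detections(dets, gt, model.config.num_classes,
                                   small_threshold=small_threshold)


class Trainer:
    """AdamW + cosine training with optional block-level distillation."""

    def __init__(self, model: DetectionModel, config: TrainConfig,
                 teacher=None, distill_state: DistillState | None = None):
        self.model = model
        self.config = config
        self.teacher = teacher
        self.state = distill_state
        self.d_adapter = None
        if distill_state is not None:
            if teacher is None:
                raise ValueError("distillation requires a teacher backbone")
            teacher.requires_grad_(False)
            if model.soeb is not None:
                ci_t = teacher.stage_channels[0]
                with nn.init_rng(config.seed + 5):
                    self.d_adapter = nn.Conv2d(
                        ci_t, model.soeb.config.out_channels, 1, zero_init=True)
        params = list(model.parameters())
        if self.state is not None:
            params += list(self.state.parameters())
        if self.d_adapter is not None:
            params += list(self.d_adapter.parameters())
        self.opt = nn.AdamW(params, lr=config.lr,
                            weight_decay=config.weight_decay)
        self.history: list[dict] = []

    def _lr(self, epoch: float) -> float:
        w = self.config.warmup_epochs
        scale = min(1.0, (epoch + 1) / w) if w > 0 else 1.0
        if self.config.schedule == "cosine":
            return scale * nn.cosine_lr(epoch, self.config.epochs, self.config.lr)
        return scale * self.config.lr

    def _loss_on_batch(self, batch: list[AnnotatedImage], epoch: int):
        cfg = self.config
        images = _batch_tensor(batch)
        d_blk = None
        pyr = None
        extra = nn.Tensor(0.0)
        if self.state is not None:
            with nn.no_grad():
                t_pyr = self.teacher(images)
            t_blocks = [f.data for f in t_pyr.block_features]
            bounds = schedule_alpha(epoch, cfg.epochs, self.state)
            active = set(self.state.active_blocks())
            # differentiable gates: substitution that raises the loss
            # drives its own gate logit down (adaptive α → 0)
            alphas = [p.gate_logit.sigmoid() * float(b)
                      if i in active and b > 0 else 0.0
                      for i, (p, b) in
                      enumerate(zip(self.state.pairings, bounds))]
            pyr, s_blocks = forward_student_with_substitution(
                self.model.backbone, images, t_blocks, alphas)
            per_block = distill_losses(t_blocks, s_blocks, self.state)
            # teacher constraints are an early-training device: the
            # alignment weight decays on the same schedule as the
            # substitution bound, so late training is purely task-driven
            phase = max(float(bounds[0]), 0.0)
            for w, l in zip(self.state.loss_weights, per_block):
                extra = extra + l * (float(w) * cfg.distill_weight * phase)
            self.state.update_running([float(l.data) for l in per_block])
            if self.d_adapter is not None and phase > 0.0:
                # distilled stride-4 guidance for the small-object branch
                last_s4 = self.model.backbone.config.teacher_stages[0].depth - 1
                pair = self.state.pairings[last_s4]
                tok = _descriptor_tokens(s_blocks[last_s4],
                                         self.state.descriptor_grid)
                rendered = pair.substitution(tok)
                g = self.state.descriptor_grid
                B = rendered.shape[0]
                gm = rendered.transpose(0, 2, 1).reshape(
                    B, pair.ci_teacher, min(g, s_blocks[last_s4].shape[2]),
                    min(g, s_blocks[last_s4].shape[3]))
                h4, w4 = s_blocks[last_s4].shape[2], s_blocks[last_s4].shape[3]
                fac = max(1, int(np.ceil(h4 / gm.shape[2])))
                gmap = nn.upsample_nearest(gm, fac)[:, :, :h4, :w4]
                # fades with the substitution phase, so train-time and
                # inference-time head inputs agree by the end of training
                d_blk = self.d_adapter(gmap) * phase
        feats, pyr_out, (_, img_logits) = self.model.extract(
            images, d_blk=d_blk, pyr=pyr)
        level_out = self.model.head(feats)
        shapes = {s: (o[0].shape[2], o[0].shape[3]) for s, o in level_out.items()}
        tgts = [assign_targets(img.boxes, img.labels, shapes,
                               self.model.config.num_classes) for img in batch]
        det_loss, parts = detection_loss(level_out, tgts,
                                         self.model.config.num_classes,
                                         box_weight=cfg.box_weight,
                                         ctr_weight=cfg.ctr_weight)
        # auxiliary image-level multi-label classification
        presence = np.zeros((len(batch), self.model.config.num_classes))
        for b, img in enumerate(batch):
            presence[b, np.unique(img.labels)] = 1.0 if len(img.labels) else 0.0
        img_loss = _bce_logits(img_logits, presence).mean()
        total = det_loss + img_loss * cfg.img_cls_weight + extra
        parts["img_cls"] = float(img_loss.data)
        parts["distill"] = float(extra.data)
        return total, parts

    def fit(self, train_images: list[AnnotatedImage],
            val_images: list[AnnotatedImage] | None = None) -> list[dict]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        augmenter = None
        if cfg.augment is not None:
            donors = extract_small_objects(train_images,
                                           cfg.augment.small_threshold)
            augmenter = Augmenter(cfg.augment, donor_pool=donors)
        for epoch in range(cfg.epochs):
            self.model.train()
            self.opt.lr = self._lr(epoch)
            order = rng.permutation(len(train_images))
            losses = []
            t0 = time.time()
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [train_images[i] for i in idx]
                if augmenter is not None:
                    batch = [augmenter(img, pool=train_images) for img in batch]
                total, parts = self._loss_on_batch(batch, epoch)
                if not np.isfinite(total.data) \
                        or float(total.data) > cfg.divergence_threshold:
                    raise TrainingDiverged(
                        f"loss {float(total.data):.3g} at epoch {epoch}")
                self.opt.zero_grad()
                total.backward()
                if cfg.clip_norm:
                    sq = sum(float((p.grad ** 2).sum())
                             for p in self.opt.params if p.grad is not None)
                    norm = sq ** 0.5
                    if norm > cfg.clip_norm:
                        scale = cfg.clip_norm / (norm + 1e-12)
                        for p in self.opt.params:
                            if p.grad is not None:
                                p.grad *= scale
                self.opt.step()
                losses.append(float(total.data))
            rec = {"epoch": epoch, "lr": self.opt.lr,
                   "loss": float(np.mean(losses)),
                   "time": time.time() - t0}
            if val_images and cfg.eval_every and (epoch + 1) % cfg.eval_every == 0:
                rec["val_map50"] = evaluate_model(self.model, val_images).map50
            self.history.append(rec)
        if val_images:
            rep = evaluate_model(self.model, val_images)
            self.history.append({"epoch": cfg.epochs, "final": True,
                                 "val_map50": rep.map50,
                                 "val_map_small": rep.map_small})
        return self.history


def train(model: DetectionModel, data, config: TrainConfig,
          distill: DistillState | None = None, teacher=None):
    """Convenience wrapper: split, fit, return (history, val report).

    ``data`` is a list of annotated images; the configured stratified ratio
    produces the train/val/test partition.
    """
    tr, va, _te = stratified_split(data, config.split_ratio, config.seed)
    trainer = Trainer(model, config, teacher=teacher, distill_state=distill)
    history = trainer.fit(tr, va)
    report = evaluate_model(model, va) if va else None
    return history, report
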