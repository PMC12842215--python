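"""Full detector assembly.

The deployed model is: mobile-transformer backbone → cross-scale lite
attention stacks on the stride-{4,8,16} levels → small-object enhancement
branch on the stride-4 level → anchor-free decoupled detection head on
strides {4, 8, 16}, plus a stride-32 semantic top that provides the global
context vector (for the context-conditioned SOEB kernels) and image-level
class logits.

Every width in the assembly scales with ``width_ratio`` so the same code
expresses the calibrated deployed profile (ratio 1, ≈5.6 G FLOPs / ≈3.2 M
params at 640²), the half-width distillation student, and the small desk-
scale variants used for training experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .backbone import (Backbone, BackboneConfig, FeaturePyramid, StageSpec,
                       scaled_channels)
from .csla import CslaConfig, CslaStack
from .profiler import scope
from .soeb import Soeb, SoebConfig

__all__ = ["ModelConfig", "DetectionModel", "build_model", "HEAD_STRIDES"]

HEAD_STRIDES = (4, 8, 16)


@dataclass
class ModelConfig:
    num_classes: int = 3
    width_ratio: float = 1.0
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    csla: CslaConfig = field(default_factory=CslaConfig)
    soeb: SoebConfig = field(default_factory=SoebConfig)
    use_csla: bool = True
    use_soeb: bool = True
    head_width: int = 64
    head_tower_depth: int = 1
    context_width: int = 504
    context_ffn_ratio: int = 2
    seed: int = 0

    def scaled_backbone(self) -> BackboneConfig:
        if self.width_ratio == 1.0:
            return self.backbone
        stages = [StageSpec(s.stride, scaled_channels(s.channels, self.width_ratio),
                            s.depth) for s in self.backbone.teacher_stages]
        return replace(self.backbone, teacher_stages=stages,
                       stem_channels=scaled_channels(
                           self.backbone.stem_channels, self.width_ratio))

    def scaled_csla(self) -> CslaConfig:
        dims = tuple((s, scaled_channels(c, self.width_ratio))
                     for s, c in self.csla.level_dims)
        return replace(self.csla, level_dims=dims)


class FFNBlock(nn.Module):
    def __init__(self, c: int, ratio: int):
        super().__init__()
        self.norm = nn.LayerNorm2d(c)
        self.fc1 = nn.Conv2d(c, ratio * c, 1)
        self.fc2 = nn.Conv2d(ratio * c, c, 1)

    def forward(self, x):
        return x + self.fc2(self.fc1(self.norm(x)).gelu())


class SemanticTop(nn.Module):
    """Stride-32 widening + FFN block: global context and image logits."""

    def __init__(self, cin: int, width: int, ffn_ratio: int, num_classes: int):
        super().__init__()
        self.expand = nn.Conv2d(cin, width, 1)
        self.norm = nn.LayerNorm2d(width)
        self.ffn = FFNBlock(width, ffn_ratio)
        self.classifier = nn.Linear(width, num_classes)

    def forward(self, x32):
        y = self.ffn(self.norm(self.expand(x32)))
        pooled = nn.global_avg_pool(y)
        return pooled, self.classifier(pooled)


class DetectionHead(nn.Module):
    """Anchor-free decoupled head shared across strides {4, 8, 16}."""

    def __init__(self, in_channels: dict[int, int], width: int, depth: int,
                 num_classes: int):
        super().__init__()
        self.strides = tuple(sorted(in_channels))
        self.num_classes = num_classes
        self.stems = nn.ModuleList(
            [nn.Conv2d(in_channels[s], width, 1) for s in self.strides])
        self.stem_norms = nn.ModuleList(
            [nn.LayerNorm2d(width) for _ in self.strides])

        def tower():
            mods = []
            for _ in range(depth):
                mods += [nn.Conv2d(width, width, 3, groups=width),
                         nn.Conv2d(width, width, 1), nn.GELU()]
            return nn.Sequential(mods)

        self.cls_tower = tower()
        self.reg_tower = tower()
        self.cls_pred = nn.Conv2d(width, num_classes, 1)
        self.reg_pred = nn.Conv2d(width, 4, 1)
        self.ctr_pred = nn.Conv2d(width, 1, 1)
        # focal prior: rare-positive bias on the classification logits
        self.cls_bias = nn.Parameter(np.full(num_classes, -3.0))
        self.log_scales = nn.Parameter(np.zeros(len(self.strides)))

    def forward(self, feats: dict[int, "nn.Tensor"]):
        out = {}
        for i, s in enumerate(self.strides):
            x = self.stem_norms[i](self.stems[i](feats[s]))
            c = self.cls_tower(x)
            r = self.reg_tower(x)
            cls = self.cls_pred(c) + self.cls_bias.reshape(1, -1, 1, 1)
            scale = self.log_scales[i].exp().reshape(1, 1, 1, 1)
            reg = (self.reg_pred(r) * scale).clip(-8.0, 8.0).exp() * float(s)
            ctr = self.ctr_pred(r)
            out[s] = (cls, reg, ctr)
        return out


class DetectionModel(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        wr = config.width_ratio

        def stream(tag: int):
            # per-module init streams: toggling one module leaves every
            # other module's weights bit-identical (paired comparisons)
            return nn.init_rng(np.random.default_rng([config.seed, tag]))

        with stream(0):
            self.backbone = Backbone(config.scaled_backbone(), role="teacher")
        ch = self.backbone.stage_channels
        with stream(1):
            self.csla = CslaStack(config.scaled_csla()) if config.use_csla else None
        head_in = {4: ch[0], 8: ch[1], 16: ch[2]}
        self.soeb = None
        if config.use_soeb:
            with stream(2):
                self.soeb = Soeb(config.soeb.scaled(wr))
                self.ctx_adapter = nn.Linear(ch[2], self.soeb.config.context_dim)
                self.g_adapter = nn.Conv2d(ch[1], self.soeb.config.out_channels, 1)
            head_in[4] = self.soeb.config.out_channels
        with stream(3):
            self.top = SemanticTop(ch[3], scaled_channels(config.context_width, wr),
                                   config.context_ffn_ratio, config.num_classes)
        with stream(4):
            self.head = DetectionHead(head_in,
                                      scaled_channels(config.head_width, wr),
                                      config.head_tower_depth,
                                      config.num_classes)

    # ------------------------------------------------------------------
    def extract(self, images, d_blk=None, pyr=None):
        """Forward up to head inputs; returns (head feats, pyramid, extras).

        ``pyr`` lets a distillation trainer substitute a pre-computed
        (gated) backbone pyramid.
        """
        images = nn.as_tensor(images)
        if pyr is None:
            with scope("backbone"):
                pyr = self.backbone(images)
        maps = dict(pyr.maps)
        if self.csla is not None:
            with scope("csla"):
                maps = self.csla(maps)
        with scope("top"):
            ctx_vec, img_logits = self.top(maps[32])
        feats = {4: maps[4], 8: maps[8], 16: maps[16]}
        if self.soeb is not None:
            with scope("soeb"):
                kernel_ctx = self.ctx_adapter(nn.global_avg_pool(maps[16]))
                e = self.soeb(pyr.maps[4], kernel_ctx)
                g = nn.upsample_nearest(self.g_adapter(maps[8]), 2)
                g = g[:, :, :e.shape[2], :e.shape[3]]
                u = e + self.soeb.eta.reshape(1, 1, 1, 1) * g
                if d_blk is not None:
                    if not self.training:
                        raise ValueError("distilled guidance is train-only")
                    u = u + self.soeb.mu.reshape(1, 1, 1, 1) * d_blk
                feats[4] = u
        return feats, pyr, (ctx_vec, img_logits)

    def forward(self, images, d_blk=None):
        feats, _, (ctx_vec, img_logits) = self.extract(images, d_blk=d_blk)
        with scope("head"):
            levels = self.head(feats)
        return levels, img_logits


def build_model(config: ModelConfig | None = None, **overrides) -> DetectionModel:
    config = config or ModelConfig(**overrides)
    return DetectionModel(config)
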