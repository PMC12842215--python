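"""Four-stage mobile-transformer backbone.

The feature extractor runs at strides {4, 8, 16, 32}.  Stages 1–3 are stacks
of convolutional mixing blocks (depthwise 3×3 spatial mixing followed by a
pointwise expand–project pair); the deepest stage, where the token count is
small, uses full multi-head self-attention blocks with an MLP.  The teacher
profile is {64, 96, 128, 192} channels over (2, 2, 6, 2) blocks; the
distillation student is the same structure at half width, {32, 48, 64, 96}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["StageSpec", "BackboneConfig", "FeaturePyramid", "Backbone",
           "build_backbone", "forward_features", "scaled_channels"]

STRIDES = (4, 8, 16, 32)


@dataclass(frozen=True)
class StageSpec:
    stride: int
    channels: int
    depth: int

    def __post_init__(self):
        if self.stride not in STRIDES:
            raise ValueError(f"stage stride must be one of {STRIDES}")
        if self.channels <= 0 or self.depth < 1:
            raise ValueError("stage channels must be > 0 and depth >= 1")


def _default_stages():
    return [StageSpec(4, 64, 2), StageSpec(8, 96, 2),
            StageSpec(16, 128, 6), StageSpec(32, 192, 2)]


@dataclass
class BackboneConfig:
    teacher_stages: list[StageSpec] = field(default_factory=_default_stages)
    student_width_ratio: float = 0.5
    total_blocks: int = 12
    stem_channels: int = 24
    attention_blocks: int = 2      # trailing stage-4 blocks using MHSA
    attention_heads: int = 4
    ffn_ratio: int = 4
    expand_ratio: int = 2          # pointwise expansion inside mixing blocks

    def __post_init__(self):
        strides = [s.stride for s in self.teacher_stages]
        if strides != sorted(strides) or len(set(strides)) != len(strides):
            raise ValueError("stage strides must be strictly increasing")
        if sum(s.depth for s in self.teacher_stages) != self.total_blocks:
            raise ValueError(
                f"stage depths {[s.depth for s in self.teacher_stages]} must sum "
                f"to total_blocks={self.total_blocks}")
        if self.attention_blocks > self.teacher_stages[-1].depth:
            raise ValueError("attention_blocks exceeds final stage depth")

    def channels_for(self, role: str) -> list[int]:
        ratio = 1.0 if role == "teacher" else self.student_width_ratio
        return [scaled_channels(s.channels, ratio) for s in self.teacher_stages]


def scaled_channels(c: int, ratio: float) -> int:
    return max(1, int(round(c * ratio)))


@dataclass
class FeaturePyramid:
    """Feature maps keyed by stride, plus per-block features for distillation."""

    maps: dict[int, Tensor]
    block_features: list[Tensor] = field(default_factory=list)

    def __getitem__(self, stride: int) -> Tensor:
        return self.maps[stride]

    @property
    def strides(self):
        return tuple(sorted(self.maps))


class MobileBlock(nn.Module):
    """DW3×3 → pointwise expand → GELU → pointwise project, residual."""

    def __init__(self, c: int, expand: int = 2):
        super().__init__()
        self.norm = nn.LayerNorm2d(c)
        self.dw = nn.Conv2d(c, c, 3, groups=c)
        self.pw1 = nn.Conv2d(c, expand * c, 1)
        self.pw2 = nn.Conv2d(expand * c, c, 1)

    def forward(self, x):
        y = self.norm(x)
        y = self.dw(y)
        y = self.pw2(self.pw1(y).gelu())
        return x + y


class AttentionBlock(nn.Module):
    """Pre-norm MHSA + MLP block for the low-resolution deepest stage."""

    def __init__(self, c: int, heads: int = 4, ffn_ratio: int = 4):
        super().__init__()
        if c % heads:
            raise ValueError(f"channels {c} not divisible by {heads} heads")
        self.c, self.heads = c, heads
        self.norm1 = nn.LayerNorm2d(c)
        self.qkv = nn.Linear(c, 3 * c, bias=False)
        self.proj = nn.Linear(c, c, bias=False)
        self.norm2 = nn.LayerNorm2d(c)
        self.fc1 = nn.Conv2d(c, ffn_ratio * c, 1)
        self.fc2 = nn.Conv2d(ffn_ratio * c, c, 1)

    def forward(self, x):
        B, C, H, W = x.shape
        hd = C // self.heads
        y = self.norm1(x)
        tokens = y.reshape(B, C, H * W).transpose(0, 2, 1)        # (B, N, C)
        qkv = self.qkv(tokens).reshape(B, H * W, 3, self.heads, hd)
        qkv = qkv.transpose(2, 0, 3, 1, 4)                        # (3,B,h,N,d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * (hd ** -0.5)
        out = attn.softmax(axis=-1) @ v                           # (B,h,N,d)
        out = out.transpose(0, 2, 1, 3).reshape(B, H * W, C)
        out = self.proj(out).transpose(0, 2, 1).reshape(B, C, H, W)
        x = x + out
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class Downsample(nn.Module):
    """Strided depthwise conv + pointwise width change between stages."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.dw = nn.Conv2d(cin, cin, 3, stride=2, groups=cin)
        self.pw = nn.Conv2d(cin, cout, 1)
        self.norm = nn.LayerNorm2d(cout)

    def forward(self, x):
        return self.norm(self.pw(self.dw(x)))


class Stem(nn.Module):
    """Two stride-2 steps reaching stride 4: full 3×3 then DW-separable."""

    def __init__(self, c_mid: int, c_out: int):
        super().__init__()
        self.conv1 = nn.Conv2d(3, c_mid, 3, stride=2)
        self.dw = nn.Conv2d(c_mid, c_mid, 3, stride=2, groups=c_mid)
        self.pw = nn.Conv2d(c_mid, c_out, 1)
        self.norm = nn.LayerNorm2d(c_out)

    def forward(self, x):
        return self.norm(self.pw(self.dw(self.conv1(x).gelu())))


class Backbone(nn.Module):
    def __init__(self, config: BackboneConfig, role: str = "teacher"):
        super().__init__()
        if role not in ("teacher", "student"):
            raise ValueError("role must be 'teacher' or 'student'")
        self.config = config
        self.role = role
        chans = config.channels_for(role)
        ratio = 1.0 if role == "teacher" else config.student_width_ratio
        for i, (c, spec) in enumerate(zip(chans, config.teacher_stages)):
            if spec.stride == 32 and config.attention_blocks and c % config.attention_heads:
                raise ValueError(
                    f"stage-{i} width {c} incompatible with "
                    f"{config.attention_heads} attention heads")
        self.stage_channels = chans
        self.stem = Stem(scaled_channels(config.stem_channels, ratio), chans[0])
        self.stages = nn.ModuleList()
        self.downsamples = nn.ModuleList()
        n_attn = config.attention_blocks
        for i, (c, spec) in enumerate(zip(chans, config.teacher_stages)):
            blocks = nn.ModuleList()
            for b in range(spec.depth):
                last_stage = i == len(chans) - 1
                if last_stage and b >= spec.depth - n_attn:
                    blocks.append(AttentionBlock(c, config.attention_heads,
                                                 config.ffn_ratio))
                else:
                    blocks.append(MobileBlock(c, config.expand_ratio))
            self.stages.append(blocks)
            if i + 1 < len(chans):
                self.downsamples.append(Downsample(c, chans[i + 1]))

    def forward(self, images: Tensor) -> FeaturePyramid:
        return forward_features(self, images)


def build_backbone(config: BackboneConfig, role: str) -> Backbone:
    """Instantiate the backbone at the teacher or student width profile."""
    return Backbone(config, role)


def forward_features(model: Backbone, images) -> FeaturePyramid:
    """Run the backbone, returning the stride-{4,8,16,32} pyramid.

    Per-block outputs (12 under the default depth layout) are collected for
    block-level distillation.
    """
    images = nn.as_tensor(images)
    if images.ndim != 4 or images.shape[1] != 3:
        raise ValueError(f"expected (B,3,H,W) images, got {images.shape}")
    H, W = images.shape[2:]
    if H % 32 or W % 32:
        raise ValueError(f"input {H}x{W} not divisible by 32")
    x = model.stem(images)
    maps: dict[int, Tensor] = {}
    blocks: list[Tensor] = []
    for i, stage in enumerate(model.stages):
        for blk in stage:
            x = blk(x)
            blocks.append(x)
        maps[model.config.teacher_stages[i].stride] = x
        if i < len(model.downsamples):
            x = model.downsamples[i](x)
    return FeaturePyramid(maps=maps, block_features=blocks)
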