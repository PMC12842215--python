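"""Small-object enhancement branch (SOEB).

A stride-1 parallel branch on the stride-4 feature map that preserves the
5–20 px detail of pest bodies: group-conv channel compression, a low-rank
token projection, a bank of context-conditioned depthwise kernels (one per
kernel size), a pooled local-context path mixed by a learnable gate, and a
pointwise channel-reorganization chain that expands progressively to the
output width.  Guidance features from the attention stack (and, during
training, from distillation) are added through 1×1 adapters with learnable
scalar weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["SoebConfig", "GuidanceBundle", "LowRankProjection", "Soeb",
           "soeb_forward", "lowrank_project", "fuse_guidance"]


@dataclass
class SoebConfig:
    in_channels: int = 64
    compressed: int = 48
    stack_channels: tuple[int, ...] = (64, 80, 96)
    kernel_set: tuple[int, ...] = (3, 5, 7)
    out_channels: int = 128
    context_dim: int = 96
    proj_rank_divisor: int = 8
    proj_rank: int | None = None          # explicit override of the C/8 rule
    compress_groups: int = 4
    gate_init: float = 0.5
    eta_init: float = 0.1
    mu_init: float = 0.1

    def __post_init__(self):
        self.kernel_set = tuple(self.kernel_set)
        if not self.kernel_set or any(k % 2 == 0 or k < 1 for k in self.kernel_set):
            raise ValueError("kernel_set must be non-empty odd kernel sizes")
        if not 0.0 <= self.gate_init <= 1.0:
            raise ValueError("gate_init must lie in [0, 1]")

    def scaled(self, ratio: float) -> "SoebConfig":
        from .backbone import scaled_channels as sc
        return SoebConfig(
            in_channels=sc(self.in_channels, ratio),
            compressed=sc(self.compressed, ratio),
            stack_channels=tuple(sc(c, ratio) for c in self.stack_channels),
            kernel_set=self.kernel_set,
            out_channels=sc(self.out_channels, ratio),
            context_dim=sc(self.context_dim, ratio),
            proj_rank_divisor=self.proj_rank_divisor,
            proj_rank=(self.proj_rank if self.proj_rank is not None
                       else max(1, -(-sc(self.compressed, ratio)
                                     // self.proj_rank_divisor))),
            compress_groups=self.compress_groups,
            gate_init=self.gate_init, eta_init=self.eta_init, mu_init=self.mu_init)


@dataclass
class GuidanceBundle:
    """Spatial guidance for the branch output.

    ``g_cs`` is the attention-stack feature resampled to stride 4; ``d_blk``
    is the distilled feature available only while training.
    """

    g_cs: Tensor | None = None
    d_blk: Tensor | None = None


class LowRankProjection(nn.Module):
    """Z = X W1 W2 with an explicit rank-r bottleneck (1×1 convolutions)."""

    def __init__(self, cin: int, rank: int, cout: int):
        super().__init__()
        if rank < 1:
            raise ValueError("rank must be >= 1")
        self.rank = rank
        self.w1 = nn.Conv2d(cin, rank, 1)
        self.w2 = nn.Conv2d(rank, cout, 1)

    def forward(self, x):
        return self.w2(self.w1(x))

    def effective_matrix(self) -> np.ndarray:
        w1 = self.w1.weight.data[:, :, 0, 0]   # (r, cin)
        w2 = self.w2.weight.data[:, :, 0, 0]   # (cout, r)
        return (w2 @ w1).T                     # (cin, cout)


def lowrank_project(x, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Functional token projection: (N, C) @ (C, r) @ (r, C'')."""
    x = np.asarray(x.data if isinstance(x, Tensor) else x, dtype=np.float64)
    return x @ w1 @ w2


def default_rank(c: int, divisor: int = 8) -> int:
    if c % divisor:
        raise ValueError(
            f"channels {c} not divisible by {divisor}; set the projection rank "
            f"explicitly")
    return c // divisor


class DynamicKernelBranch(nn.Module):
    """Depthwise k×k kernels generated from a global context vector.

    The generator is a bias-free linear map context_dim → k²·C, so its
    parameter count scales with k² — larger receptive fields genuinely cost
    capacity — while the per-pixel cost stays that of a depthwise conv.
    """

    def __init__(self, c: int, k: int, context_dim: int):
        super().__init__()
        self.c, self.k = c, k
        self.gen = nn.Linear(context_dim, k * k * c, bias=False,
                             gain=1.0 / math.sqrt(k * k))
        base = np.zeros((k, k))
        base[k // 2, k // 2] = 1.0    # identity-kernel bias of the generator
        self._base = base

    def forward(self, z: Tensor, context: Tensor) -> Tensor:
        B = z.shape[0]
        w = self.gen(context).reshape(B, self.c, self.k, self.k)
        w = w + nn.Tensor(self._base)
        return nn.conv2d_dynamic_dw(z, w)


class Soeb(nn.Module):
    def __init__(self, config: SoebConfig):
        super().__init__()
        self.config = config
        c0, cc = config.in_channels, config.compressed
        g = math.gcd(math.gcd(c0, cc), config.compress_groups)
        self.compress = nn.Conv2d(c0, cc, 1, groups=g)
        self.norm = nn.LayerNorm2d(cc)
        rank = (config.proj_rank if config.proj_rank is not None
                else default_rank(cc, config.proj_rank_divisor))
        self.project = LowRankProjection(cc, rank, cc)
        self.branches = nn.ModuleList(
            [DynamicKernelBranch(cc, k, config.context_dim)
             for k in config.kernel_set])
        self.gate_logit = nn.Parameter(
            np.array([math.log(config.gate_init / (1 - config.gate_init))
                      if 0 < config.gate_init < 1 else 0.0]))
        chain = []
        prev = cc
        for w in config.stack_channels:
            chain.append(nn.Conv2d(prev, w, 1))
            chain.append(nn.GELU())
            prev = w
        self.reorg = nn.Sequential(chain)
        self.out = nn.Conv2d(prev, config.out_channels, 1)
        self.out_norm = nn.LayerNorm2d(config.out_channels)
        self.eta = nn.Parameter(np.array([config.eta_init]))
        self.mu = nn.Parameter(np.array([config.mu_init]))
        # parameter-free residual: tile the input channels up to the output
        # width so the branch refines, rather than replaces, the shallow
        # feature (keeps the stride-4 gradient path open from step one)
        self.skip_gain = nn.Parameter(np.array([1.0])) \
            if config.out_channels % config.in_channels == 0 else None

    def forward(self, x4: Tensor, context: Tensor) -> Tensor:
        """Stride-4 feature (B, C_in, H, W) -> enhanced (B, C_out, H, W)."""
        if x4.shape[1] != self.config.in_channels:
            raise ValueError(
                f"SOEB expects {self.config.in_channels} input channels, "
                f"got {x4.shape[1]}")
        z = self.norm(self.compress(x4))
        z = self.project(z)
        alpha = self.gate_logit.sigmoid().reshape(1, 1, 1, 1)
        multi = self.branches[0](z, context)
        for br in self.branches[1:]:
            multi = multi + br(z, context)
        pooled = nn.avg_pool2d(z, 3, stride=1, pad=1)
        mixed = multi * alpha + pooled * (1.0 - alpha)
        e = self.out_norm(self.out(self.reorg(mixed)))
        if self.skip_gain is not None:
            reps = self.config.out_channels // self.config.in_channels
            tiled = nn.concat([x4] * reps, axis=1)
            e = e + tiled * self.skip_gain.reshape(1, 1, 1, 1)
        return e


def soeb_forward(x4, model: Soeb, context) -> Tensor:
    """Run the enhancement branch; resolution is preserved end to end."""
    return model(nn.as_tensor(x4), nn.as_tensor(context))


def fuse_guidance(e: Tensor, bundle: GuidanceBundle, model: Soeb,
                  mode: str = "train",
                  g_adapter=None, d_adapter=None) -> Tensor:
    """U = E + η·G_cs + μ·D_blk (the μ term exists only while training)."""
    if mode not in ("train", "infer"):
        raise ValueError("mode must be 'train' or 'infer'")
    if mode == "infer" and bundle.d_blk is not None:
        raise ValueError("distilled guidance supplied in inference mode")
    u = e
    if bundle.g_cs is not None:
        g = g_adapter(bundle.g_cs) if g_adapter is not None else bundle.g_cs
        u = u + model.eta.reshape(1, 1, 1, 1) * g
    if mode == "train" and bundle.d_blk is not None:
        d = d_adapter(bundle.d_blk) if d_adapter is not None else bundle.d_blk
        u = u + model.mu.reshape(1, 1, 1, 1) * d
    return u
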