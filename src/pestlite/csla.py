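"""Cross-scale lite attention (CSLA).

Attention over multi-scale pooled token sets with a rank-constrained score
path.  Queries, keys and values are projected to a compressed width
C' = C / compression_ratio; attention is evaluated on average-pooled token
sets at scales s ∈ {1, 2, 4} and the per-scale outputs are upsampled and
averaged before a pointwise projection is added back residually.

Two score paths exist:

* factorized (production): the score matrix is never materialized; learned
  rank-r factor maps with a positive feature transform give a
  linear-attention normalization, so cost is Θ(HW·r).
* explicit (testing): the full softmax attention matrix is formed, which is
  what the truncated-SVD error-bound analysis applies to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["CslaConfig", "AttentionFactor", "CslaBlock", "CslaStack",
           "project_qkv", "scale_attention", "lowrank_factorize", "fit_factors",
           "csla_forward"]

ALLOWED_RATIOS = (2, 4, 8, 16)


@dataclass
class CslaConfig:
    compression_ratio: int = 4
    scales: tuple[int, ...] = (1, 2, 4)
    rank: int | None = None               # default C'/2, set per level
    level_dims: tuple[tuple[int, int], ...] = ((4, 64), (8, 96), (16, 128))
    blocks_per_level: int = 4
    explicit_attention: bool = False
    materialize_threshold: int = 4096     # max token count for explicit mode

    def __post_init__(self):
        if self.compression_ratio not in ALLOWED_RATIOS:
            raise ValueError(f"compression_ratio must be in {ALLOWED_RATIOS}")
        if 1 not in self.scales or tuple(self.scales) != tuple(sorted(self.scales)):
            raise ValueError("scales must be ascending and contain 1")

    def compressed(self, c: int) -> int:
        if c % self.compression_ratio:
            raise ValueError(
                f"channels {c} not divisible by compression ratio "
                f"{self.compression_ratio}")
        return c // self.compression_ratio

    def rank_for(self, c: int) -> int:
        return self.rank if self.rank is not None else max(1, self.compressed(c) // 2)


@dataclass
class AttentionFactor:
    """Rank-r factorization A ≈ U Vᵀ with the discarded singular tail."""

    U: np.ndarray
    V: np.ndarray
    singular_tail: np.ndarray

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.U @ self.V.T

    def error_bound(self) -> float:
        """Eckart–Young tail bound on the Frobenius approximation error."""
        return float(self.singular_tail.sum())


# ---------------------------------------------------------------------------
# Functional operations
# ---------------------------------------------------------------------------

def project_qkv(x, wq, wk, wv):
    """Project a (C, H, W) or (HW, C) feature to compact Q, K, V token sets.

    Returns three (HW, C') arrays given projection matrices of shape (C, C').
    """
    x = np.asarray(x.data if isinstance(x, Tensor) else x, dtype=np.float64)
    if x.ndim == 3:
        c = x.shape[0]
        tokens = x.reshape(c, -1).T
    elif x.ndim == 2:
        tokens = x
    else:
        raise ValueError("expected (C,H,W) map or (N,C) tokens")
    if tokens.shape[1] != wq.shape[0]:
        raise ValueError(f"feature width {tokens.shape[1]} does not match "
                         f"projection rows {wq.shape[0]}")
    return tokens @ wq, tokens @ wk, tokens @ wv


def _pool_tokens(tokens: np.ndarray, s: int, spatial) -> np.ndarray:
    if s == 1:
        return tokens
    if spatial is None:
        raise ValueError("pooling factor > 1 requires the spatial shape")
    h, w = spatial
    c = tokens.shape[1]
    grid = tokens.reshape(h, w, c)
    ho, wo = h // s, w // s
    if ho == 0 or wo == 0:
        raise ValueError(f"token grid {h}x{w} too small for scale {s}")
    return grid[:ho * s, :wo * s].reshape(ho, s, wo, s, c).mean(axis=(1, 3)) \
        .reshape(ho * wo, c)


def scale_attention(q, k, v, s: int = 1, d_s: int | None = None, spatial=None):
    """Softmax attention over factor-s pooled token sets.

    Returns (attended tokens, attention matrix); rows of the matrix sum to 1.
    """
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    qs, ks, vs = (_pool_tokens(a, s, spatial) for a in (q, k, v))
    if qs.shape[0] == 0 or ks.shape[0] == 0:
        raise ValueError("empty token set")
    d = d_s if d_s is not None else qs.shape[1]
    scores = qs @ ks.T / np.sqrt(d)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=1, keepdims=True)
    return attn @ vs, attn


def lowrank_factorize(a: np.ndarray, r: int) -> AttentionFactor:
    """Best rank-r factorization (truncated SVD) of a score matrix.

    The stored singular tail Σ_{i>r} σ_i upper-bounds the Frobenius error of
    *any* rank-r approximation path used in the attention module.
    """
    a = np.asarray(a, dtype=np.float64)
    if r < 1:
        raise ValueError("rank must be >= 1")
    if r >= min(a.shape):
        import warnings
        warnings.warn("rank >= min(n, m): factorization is exact, no compression",
                      stacklevel=2)
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    r_eff = min(r, len(s))
    sq = np.sqrt(s[:r_eff])
    return AttentionFactor(U=u[:, :r_eff] * sq, V=(vt[:r_eff].T * sq),
                           singular_tail=s[r_eff:])


def fit_factors(a: np.ndarray, r: int, steps: int = 200, lr: float = 0.05,
                seed: int = 0) -> AttentionFactor:
    """Gradient-learned rank-r factors (the production path's training proxy).

    By Eckart–Young the achievable error is bounded below by the truncated
    SVD, which tests verify.
    """
    a = np.asarray(a, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n, m = a.shape
    u = rng.normal(0, 0.1, (n, r))
    v = rng.normal(0, 0.1, (m, r))
    for _ in range(steps):
        resid = u @ v.T - a
        gu = resid @ v / m
        gv = resid.T @ u / n
        u -= lr * gu
        v -= lr * gv
    s = np.linalg.svd(a, compute_uv=False)
    return AttentionFactor(U=u, V=v, singular_tail=s[min(r, len(s)):])


def _softplus(x: Tensor) -> Tensor:
    # numerically stable positive feature map for linear attention
    return x.relu() + ((-x.abs()).exp() + 1.0).log()


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class CslaBlock(nn.Module):
    def __init__(self, c: int, config: CslaConfig):
        super().__init__()
        cp = config.compressed(c)
        r = config.rank_for(c)
        self.c, self.cp, self.r = c, cp, r
        self.config = config
        self.norm = nn.LayerNorm2d(c)
        self.local = nn.Conv2d(c, c, 3, groups=c)
        self.q = nn.Conv2d(c, cp, 1)
        self.k = nn.Conv2d(c, cp, 1)
        self.v = nn.Conv2d(c, cp, 1)
        self.factor_u = nn.Conv2d(cp, r, 1)
        self.factor_v = nn.Conv2d(cp, r, 1)
        # zero-init output projection: each block starts as the exact
        # residual identity, keeping deep stacks stable and letting the
        # attention path grow only where it reduces the loss
        self.out = nn.Conv2d(cp, c, 1, zero_init=True)

    def _scale_out(self, q, k, v, s: int, H: int, W: int):
        B = q.shape[0]
        if s > 1:
            o_h, o_w = -(-H // s), -(-W // s)
            pad_h = max(0, (s * o_h - H + 1) // 2)
            q, k, v = (nn.avg_pool2d(t, s, stride=s, pad=pad_h) for t in (q, k, v))
        hs, ws = q.shape[2], q.shape[3]
        n = hs * ws
        if self.config.explicit_attention:
            if n > self.config.materialize_threshold:
                raise RuntimeError(
                    f"explicit attention refused for {n} tokens "
                    f"(> {self.config.materialize_threshold})")
            qt = q.reshape(B, self.cp, n).transpose(0, 2, 1)
            kt = k.reshape(B, self.cp, n).transpose(0, 2, 1)
            vt = v.reshape(B, self.cp, n).transpose(0, 2, 1)
            attn = ((qt @ kt.transpose(0, 2, 1)) * (self.cp ** -0.5)).softmax(-1)
            out = attn @ vt
        else:
            scale = float(self.cp) ** -0.25
            U = _softplus(self.factor_u(q * scale))     # (B, r, hs, ws)
            F = _softplus(self.factor_v(k * scale))
            U = U.reshape(B, self.r, n).transpose(0, 2, 1)       # (B, n, r)
            F = F.reshape(B, self.r, n)                          # (B, r, n)
            vt = v.reshape(B, self.cp, n).transpose(0, 2, 1)     # (B, n, cp)
            kv = F @ vt                                          # (B, r, cp)
            z = U @ kv                                           # (B, n, cp)
            denom = U @ F.sum(axis=2, keepdims=True) + 1e-6      # (B, n, 1)
            out = z / denom
        out = out.transpose(0, 2, 1).reshape(B, self.cp, hs, ws)
        if s > 1:
            out = nn.upsample_nearest(out, s)[:, :, :H, :W]
        return out

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        y = self.local(self.norm(x))
        q, k, v = self.q(y), self.k(y), self.v(y)
        outs = [self._scale_out(q, k, v, s, H, W) for s in self.config.scales]
        merged = outs[0]
        for o in outs[1:]:
            merged = merged + o
        merged = merged * (1.0 / len(outs))
        return x + self.out(merged)


class CslaLevel(nn.Module):
    def __init__(self, stride: int, c: int, config: CslaConfig):
        super().__init__()
        self.stride, self.c = stride, c
        self.blocks = nn.ModuleList(
            [CslaBlock(c, config) for _ in range(config.blocks_per_level)])

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c:
            raise ValueError(
                f"CSLA level at stride {self.stride} expects {self.c} channels, "
                f"got {x.shape[1]}")
        for blk in self.blocks:
            x = blk(x)
        return x


class CslaStack(nn.Module):
    """Per-level CSLA stacks applied to the stride-{4,8,16} pyramid levels."""

    def __init__(self, config: CslaConfig):
        super().__init__()
        self.config = config
        self.levels = nn.ModuleList()
        self.level_dims = tuple(config.level_dims)
        for stride, c in self.level_dims:
            self.levels.append(CslaLevel(stride, c, config))

    def forward(self, maps: dict[int, Tensor]) -> dict[int, Tensor]:
        out = dict(maps)
        for level in self.levels:
            if level.stride not in maps:
                raise ValueError(f"pyramid missing stride {level.stride}")
            out[level.stride] = level(maps[level.stride])
        return out


def csla_forward(x, level: CslaLevel) -> Tensor:
    """Residual CSLA transform of one pyramid level: Y = X + f(X)."""
    return level(nn.as_tensor(x))
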