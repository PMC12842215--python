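"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based autodiff engine: every :class:`Tensor` wraps an
``ndarray`` and remembers the closure that propagates gradients to its
parents.  Only the operations the detection stack needs are implemented —
dense/grouped/depthwise convolution via im2col, matmul, elementwise math,
reductions, pooling, nearest upsampling and slicing.  All arithmetic is
float64, so two runs from the same seed are bitwise identical.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]

# Optional multiply-accumulate hook; the profiler installs a callable here so
# that convolution and matmul report exactly the MACs they execute.
_MAC_HOOK: list = [None]


def _mac(count: int):
    hook = _MAC_HOOK[-1]
    if hook is not None:
        hook(int(count))


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # ---- plumbing -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=False)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go
                node._backward = None
                node._parents = ()

    # ---- elementwise ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(self.data ** p, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / np.maximum(o, 1e-12))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bwd)

    def gelu(self):
        # exact Gaussian-error-function form
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))

        def bwd(g, a=self, cdf=cdf):
            x = a.data
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            if a.requires_grad:
                a._accum(g * (cdf + x * pdf))

        return self._make(x * cdf, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(self.data * mask, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g, a=self, s=sign):
            if a.requires_grad:
                a._accum(g * s)

        return self._make(np.abs(self.data), (self,), bwd)

    def arctan(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / (1.0 + a.data ** 2))

        return self._make(np.arctan(self.data), (self,), bwd)

    def clip(self, lo: float | None, hi: float | None):
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(np.clip(self.data, lo, hi), (self,), bwd)

    # ---- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy()
                         if np.ndim(g) == 0 or g.shape != a.data.shape
                         else g)
                return
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(x % a.data.ndim for x in ax)
                shape = [1 if i in ax else s for i, s in enumerate(a.data.shape)]
                g = g.reshape(shape)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = self.data == expanded
        count = mask.sum(axis=axis, keepdims=True)

        def bwd(g, a=self, axis=axis, keepdims=keepdims, mask=mask, count=count):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(x % a.data.ndim for x in ax)
                shape = [1 if i in ax else s for i, s in enumerate(a.data.shape)]
                g = np.asarray(g).reshape(shape)
            a._accum(mask * (g / count))

        return self._make(out_data, (self,), bwd)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(self.data[idx], (self,), bwd)

    # ---- linear algebra --------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        _mac(out_data.size * self.data.shape[-1])

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(out_data, (self, other), bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g, a=self, s=s, axis=axis):
            if a.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                a._accum(s * (g - dot))

        return self._make(s, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g, parts=tensors, sizes=sizes, axis=axis):
        offs = np.cumsum([0] + sizes)
        for t, lo, hi in zip(parts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = tensors[0]._make(out_data, tuple(tensors), bwd)
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g, parts=tensors, axis=axis):
        for i, t in enumerate(parts):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return tensors[0]._make(out_data, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# Spatial ops (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, K: int, stride: int, pad: int):
    B, C, H, W = x.shape
    Ho = (H + 2 * pad - K) // stride + 1
    Wo = (W + 2 * pad - K) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(B, C, Ho, Wo, K, K),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    # (B, C*K*K, Ho*Wo)
    col = windows.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * K * K, Ho * Wo)
    return np.ascontiguousarray(col), Ho, Wo


def _col2im(col: np.ndarray, x_shape, K: int, stride: int, pad: int):
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - K) // stride + 1
    Wo = (Wp - K) // stride + 1
    xg = np.zeros((B, C, Hp, Wp))
    col = col.reshape(B, C, K, K, Ho, Wo)
    for i in range(K):
        hmax = i + stride * Ho
        for j in range(K):
            wmax = j + stride * Wo
            xg[:, :, i:hmax:stride, j:wmax:stride] += col[:, :, i, j]
    if pad:
        xg = xg[:, :, pad:-pad, pad:-pad]
    return xg


def _windows(x: np.ndarray, K: int, stride: int, pad: int):
    """Strided (B, C, Ho, Wo, K, K) sliding-window view (no copy)."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (x.shape[2] - K) // stride + 1
    Wo = (x.shape[3] - K) // stride + 1
    s = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(B, C, Ho, Wo, K, K),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False), Ho, Wo


def _depthwise_conv(x: Tensor, w: Tensor, stride: int, pad: int):
    """Fast path for groups == Cin == Cout (kernel shape (C, 1, K, K))."""
    B, C, H, W = x.shape
    K = w.shape[2]
    win, Ho, Wo = _windows(x.data, K, stride, pad)
    kern = w.data[:, 0]                                  # (C, K, K)
    out = np.einsum("bchwij,cij->bchw", win, kern, optimize=True)
    _mac(B * C * K * K * Ho * Wo)

    def bwd(g, x=x, w=w, win=win, kern=kern, stride=stride, pad=pad, K=K,
            shape=(B, C, H, W)):
        if w.requires_grad:
            gw = np.einsum("bchwij,bchw->cij", win, g, optimize=True)
            w._accum(gw[:, None])
        if x.requires_grad:
            B_, C_, H_, W_ = shape
            Hp, Wp = H_ + 2 * pad, W_ + 2 * pad
            Ho, Wo = g.shape[2], g.shape[3]
            gx = np.zeros((B_, C_, Hp, Wp))
            for i in range(K):
                for j in range(K):
                    gx[:, :, i:i + stride * Ho:stride,
                       j:j + stride * Wo:stride] += g * kern[:, i, j][:, None, None]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    return x._make(out, (x, w), bwd), Ho, Wo


def conv2d(x: Tensor, w: Tensor, stride: int = 1, pad: int | None = None,
           groups: int = 1) -> Tensor:
    """Grouped 2-D convolution; ``w`` has shape (Cout, Cin//groups, K, K)."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.shape
    Cout, Cin_g, K, _ = w.shape
    if C % groups or Cout % groups or Cin_g != C // groups:
        raise ValueError(
            f"conv2d: channels ({C}->{Cout}) not compatible with groups={groups}")
    if pad is None:
        pad = K // 2
    if groups == C and Cout == C:
        return _depthwise_conv(x, w, stride, pad)[0]
    if K == 1 and stride == 1 and pad == 0 and groups == 1:
        # pointwise fast path: a matmul over flattened positions
        out = np.einsum("oc,bchw->bohw", w.data[:, :, 0, 0], x.data,
                        optimize=True)
        _mac(B * Cout * C * H * W)

        def bwd1(g, x=x, w=w):
            if w.requires_grad:
                gw = np.einsum("bohw,bchw->oc", g, x.data, optimize=True)
                w._accum(gw[:, :, None, None])
            if x.requires_grad:
                x._accum(np.einsum("oc,bohw->bchw", w.data[:, :, 0, 0], g,
                                   optimize=True))

        return x._make(out, (x, w), bwd1)
    col, Ho, Wo = _im2col(x.data, K, stride, pad)          # (B, C*K*K, L)
    L = Ho * Wo
    colg = col.reshape(B, groups, Cin_g * K * K, L)
    wg = w.data.reshape(groups, Cout // groups, Cin_g * K * K)
    out = np.einsum("gok,bgkl->bgol", wg, colg, optimize=True)
    out = out.reshape(B, Cout, Ho, Wo)
    _mac(B * Cout * (C // groups) * K * K * L)

    def bwd(g, x=x, w=w, colg=colg, wg=wg, stride=stride, pad=pad,
            groups=groups, K=K, shape=(B, C, H, W), Ho=Ho, Wo=Wo):
        gg = g.reshape(shape[0], groups, w.shape[0] // groups, Ho * Wo)
        if w.requires_grad:
            gw = np.einsum("bgol,bgkl->gok", gg, colg, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcol = np.einsum("gok,bgol->bgkl", wg, gg, optimize=True)
            gcol = gcol.reshape(shape[0], -1, Ho * Wo)
            x._accum(_col2im(gcol, shape, K, stride, pad))

    return x._make(out, (x, w), bwd)


def conv2d_dynamic_dw(x: Tensor, wdyn: Tensor, pad: int | None = None) -> Tensor:
    """Depthwise conv with a per-sample kernel ``wdyn`` of shape (B, C, K, K).

    Folds the batch into the channel axis so a single grouped convolution
    handles all samples; used by the context-conditioned kernels of the
    small-object branch.
    """
    x, wdyn = as_tensor(x), as_tensor(wdyn)
    B, C, H, W = x.shape
    Bw, Cw, K, _ = wdyn.shape
    if (Bw, Cw) != (B, C):
        raise ValueError("dynamic kernel batch/channels mismatch")
    xr = x.reshape(1, B * C, H, W)
    wr = wdyn.reshape(B * C, 1, K, K)
    out = conv2d(xr, wr, stride=1, pad=pad, groups=B * C)
    return out.reshape(B, C, H, W)


def avg_pool2d(x: Tensor, k: int, stride: int | None = None, pad: int = 0) -> Tensor:
    """Average pooling implemented as a fixed uniform depthwise kernel."""
    x = as_tensor(x)
    stride = stride or k
    C = x.shape[1]
    kernel = Tensor(np.full((C, 1, k, k), 1.0 / (k * k)))
    return conv2d(x, kernel, stride=stride, pad=pad, groups=C)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def bwd(g, x=x, f=factor, B=B, C=C, H=H, W=W):
        if x.requires_grad:
            g = g.reshape(B, C, H, f, W, f).sum(axis=(3, 5))
            x._accum(g)

    return x._make(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C)"""
    return x.mean(axis=(2, 3))


def _pool_segments(n: int, g: int):
    edges = np.linspace(0, n, g + 1)
    lo = np.floor(edges[:-1]).astype(int)
    hi = np.ceil(edges[1:]).astype(int)
    return lo, hi


def adaptive_avg_pool2d(x: Tensor, gh: int, gw: int) -> Tensor:
    """Average-pool an NCHW map to an exact (gh, gw) grid (pure additions,
    no multiply-accumulates)."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    gh, gw = min(gh, H), min(gw, W)
    hlo, hhi = _pool_segments(H, gh)
    wlo, whi = _pool_segments(W, gw)
    csum = x.data.cumsum(axis=2).cumsum(axis=3)
    pad = np.zeros((B, C, H + 1, W + 1))
    pad[:, :, 1:, 1:] = csum
    out = (pad[:, :, hhi][:, :, :, whi] - pad[:, :, hlo][:, :, :, whi]
           - pad[:, :, hhi][:, :, :, wlo] + pad[:, :, hlo][:, :, :, wlo])
    area = ((hhi - hlo)[:, None] * (whi - wlo)[None, :]).astype(float)
    out = out / area

    def bwd(g, x=x, hlo=hlo, hhi=hhi, wlo=wlo, whi=whi, area=area,
            shape=(B, C, H, W)):
        if not x.requires_grad:
            return
        gx = np.zeros(shape)
        gn = g / area
        for i in range(len(hlo)):
            for j in range(len(wlo)):
                gx[:, :, hlo[i]:hhi[i], wlo[j]:whi[j]] += gn[:, :, i:i+1, j:j+1]
        x._accum(gx)

    return x._make(out, (x,), bwd)
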