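"""Module system and common layers built on the autodiff core."""

from __future__ import annotations

import contextlib
import math
from typing import Iterator

import numpy as np

from .core import Tensor, avg_pool2d, conv2d, global_avg_pool

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential", "Identity",
    "Conv2d", "Linear", "LayerNorm2d", "GELU", "Sigmoid",
    "init_rng", "current_rng",
]

_RNG_STACK = [np.random.default_rng(0)]


@contextlib.contextmanager
def init_rng(seed_or_rng):
    """Scope the random stream used for weight initialization."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    _RNG_STACK.append(rng)
    try:
        yield rng
    finally:
        _RNG_STACK.pop()


def current_rng() -> np.random.Generator:
    return _RNG_STACK[-1]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: attribute assignment registers children/params."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._children[key] = value
        object.__setattr__(self, key, value)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, child in self._children.items():
            yield from child.named_parameters(prefix + k + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self._children.values():
            yield from child.modules()

    def named_children(self):
        return self._children.items()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def requires_grad_(self, flag: bool = True):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        key = str(len(self._list))
        self._list.append(mod)
        self._children[key] = mod
        object.__setattr__(self, key, mod)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """Bias-free grouped convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 pad: int | None = None, groups: int = 1, zero_init: bool = False,
                 gain: float = 1.0):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError(f"channels {cin}->{cout} not divisible by groups={groups}")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.groups = stride, groups
        self.pad = k // 2 if pad is None else pad
        fan_in = cin // groups * k * k
        w = current_rng().normal(0.0, gain * math.sqrt(2.0 / fan_in),
                                 size=(cout, cin // groups, k, k))
        if zero_init:
            w = np.zeros_like(w)
        self.weight = Parameter(w)

    def forward(self, x):
        return conv2d(x, self.weight, stride=self.stride, pad=self.pad,
                      groups=self.groups)

    def flops(self, h_out: int, w_out: int) -> int:
        return self.cin * self.cout * self.k * self.k * h_out * w_out // self.groups


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True, gain: float = 1.0,
                 zero_init: bool = False):
        super().__init__()
        self.cin, self.cout = cin, cout
        w = current_rng().normal(0.0, gain * math.sqrt(2.0 / cin), size=(cin, cout))
        if zero_init:
            w = np.zeros_like(w)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm2d(Module):
    """Channel-wise layer norm for NCHW maps (normalizes over C per position)."""

    eps = 1e-5

    def __init__(self, c: int):
        super().__init__()
        self.c = c
        self.gamma = Parameter(np.ones((1, c, 1, 1)))
        self.beta = Parameter(np.zeros((1, c, 1, 1)))

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()
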