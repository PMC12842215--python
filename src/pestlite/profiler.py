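"""Parameter and FLOPs accounting.

FLOPs are multiply–accumulates (one MAC = one FLOP, the convention used by
common detector profilers); counts are gathered by instrumenting the
convolution and matmul kernels while a real forward pass runs, so the
numbers reflect exactly the executed graph.  Counts are independent of
weight values, and "G FLOPs" means MACs / 1e9.

A ``simplified_layer_flops`` helper reproduces the simplified textbook
per-layer formula ``C·H·W·K²`` (which drops the input-channel factor) for
transparency; calibration and reports use the standard MAC count.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.core import _MAC_HOOK

__all__ = ["ProfileReport", "count_conv_flops", "simplified_layer_flops",
           "profile_model", "profile_callable", "blsd_overhead", "scope"]

_SCOPE_STACK: list[str] = []
_ACTIVE: list[dict | None] = [None]


@contextlib.contextmanager
def scope(name: str):
    """Label MACs recorded inside this context (nested names join with '.')."""
    _SCOPE_STACK.append(name)
    try:
        yield
    finally:
        _SCOPE_STACK.pop()


def _record(count: int):
    acc = _ACTIVE[-1]
    if acc is None:
        return
    key = _SCOPE_STACK[0] if _SCOPE_STACK else "(unscoped)"
    acc[key] = acc.get(key, 0) + count
    acc["total"] = acc.get("total", 0) + count


@dataclass
class ProfileReport:
    total_params: int
    total_flops: int
    input_size: tuple[int, int]
    per_module_flops: dict[str, int] = field(default_factory=dict)
    per_module_params: dict[str, int] = field(default_factory=dict)
    blsd_overhead_fraction: float = 0.0

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    @property
    def mparams(self) -> float:
        return self.total_params / 1e6

    def table(self) -> str:
        rows = [f"{'module':<16}{'GFLOPs':>10}{'params':>12}"]
        for k in sorted(set(self.per_module_flops) | set(self.per_module_params)):
            rows.append(f"{k:<16}{self.per_module_flops.get(k, 0) / 1e9:>10.3f}"
                        f"{self.per_module_params.get(k, 0):>12d}")
        rows.append(f"{'total':<16}{self.gflops:>10.3f}{self.total_params:>12d}")
        return "\n".join(rows)


def count_conv_flops(c_in: int, c_out: int, h_out: int, w_out: int, k: int,
                     groups: int = 1) -> int:
    """MACs of one convolution layer: C_in·C_out·H·W·K² / groups."""
    if min(c_in, c_out, h_out, w_out, k) < 1:
        raise ValueError("dimensions must be positive")
    if c_in % groups or c_out % groups:
        raise ValueError(f"groups={groups} must divide channels")
    return c_in * c_out * h_out * w_out * k * k // groups


def simplified_layer_flops(c_out: int, h_out: int, w_out: int, k: int) -> int:
    """The simplified per-layer count C·H·W·K² (input channels omitted)."""
    return c_out * h_out * w_out * k * k


def profile_callable(fn, *args) -> dict[str, int]:
    """Run ``fn(*args)`` while counting MACs; returns per-scope counts."""
    acc: dict[str, int] = {"total": 0}
    _ACTIVE.append(acc)
    _MAC_HOOK.append(_record)
    try:
        with nn.no_grad():
            fn(*args)
    finally:
        _MAC_HOOK.pop()
        _ACTIVE.pop()
    return acc


def profile_model(model, input_size: int | tuple[int, int] = 640,
                  batch: int = 1) -> ProfileReport:
    """Profile one forward pass of a detection model (or any module taking
    an image batch) at the given input size."""
    if isinstance(input_size, int):
        input_size = (input_size, input_size)
    h, w = input_size
    if h % 32 or w % 32:
        raise ValueError(f"input {h}x{w} must be divisible by 32")
    images = np.zeros((batch, 3, h, w))
    counts = profile_callable(model, images)
    total = counts.pop("total") // batch
    per_mod_flops = {k: v // batch for k, v in counts.items()}
    per_params: dict[str, int] = {}
    for name, child in getattr(model, "named_children", lambda: [])():
        per_params[name] = child.num_parameters()
    own = model.num_parameters()
    return ProfileReport(total_params=own, total_flops=total,
                         input_size=(h, w), per_module_flops=per_mod_flops,
                         per_module_params=per_params)


def blsd_overhead(trainer_or_state, backbone, input_size=640,
                  student=None) -> float:
    """Training-graph FLOPs added by the distillation paths, as a fraction
    of backbone FLOPs.

    ``trainer_or_state`` is a DistillState (or None for a never-distilled
    model, giving exactly 0).  The inference graph contains none of these
    modules, so inference overhead is identically zero.
    """
    if trainer_or_state is None:
        return 0.0
    state = trainer_or_state
    if isinstance(input_size, int):
        input_size = (input_size, input_size)
    h, w = input_size
    images = np.zeros((1, 3, h, w))
    base = profile_callable(backbone, images)["total"]

    stu = student if student is not None else backbone

    # measure: (teacher + student + distill paths) - (teacher + student)
    def full():
        t_pyr = backbone(nn.as_tensor(images))
        s_pyr = stu(nn.as_tensor(images))
        from .blsd import distill_losses, _descriptor_tokens
        t_blocks = [f.data for f in t_pyr.block_features]
        distill_losses(t_blocks, s_pyr.block_features, state)
        for idx in state.active_blocks():
            pair = state.pairings[idx]
            tok = _descriptor_tokens(s_pyr.block_features[idx],
                                     state.descriptor_grid)
            pair.substitution(tok)

    def plain():
        backbone(nn.as_tensor(images))
        stu(nn.as_tensor(images))

    extra = profile_callable(full)["total"] - profile_callable(plain)["total"]
    return extra / base
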