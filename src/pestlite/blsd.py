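"""Block-level substitution distillation (BLSD).

A frozen teacher and a half-width student share the same 12-block layout at
identical spatial resolutions.  Three mechanisms transfer teacher semantics:

* per-block alignment — student features are mapped to teacher width by a
  trainable linear matrix M_i and penalized by the squared substitution
  error ||T_i − S_i M_i||²;
* gated substitution — early in training the input of block k is the convex
  mix Z_k = α_k·T_{k−1} + (1−α_k)·S_{k−1} (teacher features adapted to
  student width by a frozen parameter-free pairwise-mean projection); the
  schedule drives the α upper bound to zero so the path vanishes;
* substitution blocks — a two-linear-layer expansion path (ratio 4) with a
  scale-shift modulation that renders student block descriptors in teacher
  width; its output also serves as the distilled guidance injected into the
  small-object branch while training.

All alignment statistics are computed on a fixed pooled descriptor grid per
block, which keeps the distillation cost independent of input resolution (a
few percent of backbone compute).  Nothing here is part of the inference
graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import Backbone

__all__ = ["BlockPairing", "DistillState", "map_student_feature", "block_loss",
           "gate_mix", "schedule_alpha", "substitution_block_params",
           "distill_step", "adapt_teacher_channels", "pool_to_grid",
           "forward_student_with_substitution"]


def substitution_block_params(ci_student: int, r: int, ci_teacher: int) -> int:
    """Closed-form parameter count of the bias-free two-linear expansion path."""
    if min(ci_student, r, ci_teacher) < 1:
        raise ValueError("dimensions must be positive")
    hidden = r * ci_student
    return ci_student * hidden + hidden * ci_teacher


class SubstitutionBlock(nn.Module):
    """Linear(C'→rC') → GELU → Linear(rC'→C) with scale-shift modulation."""

    def __init__(self, ci_student: int, ci_teacher: int, expansion: int = 4):
        super().__init__()
        hidden = expansion * ci_student
        self.fc1 = nn.Linear(ci_student, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, ci_teacher, bias=False)
        self.mod_scale = nn.Parameter(np.zeros(ci_teacher))
        self.mod_shift = nn.Parameter(np.zeros(ci_teacher))

    def forward(self, tokens: Tensor) -> Tensor:
        y = self.fc2(self.fc1(tokens).gelu())
        return y * (1.0 + self.mod_scale) + self.mod_shift


class BlockPairing(nn.Module):
    def __init__(self, index: int, ci_teacher: int, ci_student: int,
                 expansion: int = 4, gate_init: float = -2.0):
        super().__init__()
        self.index = index
        self.ci_teacher = ci_teacher
        self.ci_student = ci_student
        self.mapping = nn.Linear(ci_student, ci_teacher, bias=False)
        # conservative start (sigmoid of the init logit scales the bound);
        # the logit is trained, so harmful substitution closes itself
        self.gate_logit = nn.Parameter(np.full(1, gate_init))
        self.substitution = SubstitutionBlock(ci_student, ci_teacher, expansion)

    def gate_value(self, bound: float) -> float:
        return float(bound / (1.0 + np.exp(-self.gate_logit.data[0])))


class DistillState(nn.Module):
    """Teacher/student block pairings plus the substitution schedule."""

    def __init__(self, teacher: Backbone, student: Backbone,
                 expansion_ratio: int = 4, substitution_end_fraction: float = 0.5,
                 top_m: int = 4, descriptor_grid: int = 10,
                 loss_weights=None, gate_init: float = -2.0):
        super().__init__()
        t_ch = _block_channels(teacher)
        s_ch = _block_channels(student)
        if len(t_ch) != len(s_ch):
            raise ValueError("teacher/student block counts differ")
        self.expansion_ratio = expansion_ratio
        self.substitution_end_fraction = substitution_end_fraction
        self.top_m = top_m
        self.descriptor_grid = descriptor_grid
        self.pairings = nn.ModuleList(
            [BlockPairing(i, ct, cs, expansion_ratio, gate_init=gate_init)
             for i, (ct, cs) in enumerate(zip(t_ch, s_ch))])
        n = len(t_ch)
        self.loss_weights = np.ones(n) if loss_weights is None \
            else np.asarray(loss_weights, dtype=float)
        self.running_loss = np.zeros(n)

    def __len__(self):
        return len(self.pairings)

    def active_blocks(self) -> list[int]:
        """Indices eligible for substitution: top-m by running block loss."""
        order = np.argsort(-self.running_loss, kind="stable")
        return sorted(int(i) for i in order[: self.top_m])

    def update_running(self, losses):
        self.running_loss = 0.9 * self.running_loss + 0.1 * np.asarray(losses)


def _block_channels(backbone: Backbone) -> list[int]:
    out = []
    for c, spec in zip(backbone.stage_channels, backbone.config.teacher_stages):
        out.extend([c] * spec.depth)
    return out


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def map_student_feature(si, mi) -> Tensor:
    """T̂_i = S_i M_i — linear channel alignment, spatial layout untouched."""
    si = nn.as_tensor(si)
    mi = mi.weight if isinstance(mi, nn.Linear) else nn.as_tensor(mi)
    if si.shape[-1] != mi.shape[0]:
        raise ValueError(
            f"block feature width {si.shape[-1]} does not match mapping rows "
            f"{mi.shape[0]}")
    return si @ mi


def block_loss(ti, ti_hat) -> Tensor:
    """Squared substitution error ||T_i − T̂_i||²₂ (sum over all entries)."""
    ti, ti_hat = nn.as_tensor(ti), nn.as_tensor(ti_hat)
    if ti.shape != ti_hat.shape:
        raise ValueError("teacher and mapped student features must match")
    d = ti - ti_hat
    return (d * d).sum()


def gate_mix(t_prev, s_prev, alpha: float) -> Tensor:
    """Z_k = α_k T_{k−1} + (1−α_k) S_{k−1} (exact convex combination)."""
    if not 0.0 <= alpha <= 1.0:
        warnings.warn(f"gate α={alpha} outside [0,1]; clamped", stacklevel=2)
        alpha = min(max(alpha, 0.0), 1.0)
    t_prev, s_prev = nn.as_tensor(t_prev), nn.as_tensor(s_prev)
    if t_prev.shape != s_prev.shape:
        raise ValueError("gate_mix operands must be channel-matched")
    return t_prev * alpha + s_prev * (1.0 - alpha)


def schedule_alpha(epoch: int, total_epochs: int, state: DistillState) -> np.ndarray:
    """Per-block upper bounds on α_k: linear decay reaching 0 at the
    configured fraction of training, zero afterwards."""
    if not 0 <= epoch < max(total_epochs, 1):
        raise ValueError("epoch out of range")
    end = state.substitution_end_fraction * total_epochs
    bound = 0.0 if end <= 0 or epoch >= end else 1.0 - epoch / end
    return np.full(len(state), bound)


def adapt_teacher_channels(t: np.ndarray, c_student: int) -> np.ndarray:
    """Frozen parameter-free projection teacher→student width.

    Channels are grouped evenly and averaged (rows of the implied projection
    are orthogonal); for the default half-width student this is a pairwise
    mean.
    """
    B, C, H, W = t.shape
    if C % c_student:
        raise ValueError(f"teacher width {C} not divisible by student width "
                         f"{c_student}")
    g = C // c_student
    return t.reshape(B, c_student, g, H, W).mean(axis=2)


def pool_to_grid(x: Tensor, grid: int) -> Tensor:
    """Adaptive average pooling of an NCHW map to a (grid × grid) descriptor."""
    return nn.core.adaptive_avg_pool2d(nn.as_tensor(x), grid, grid)


def _descriptor_tokens(x: Tensor, grid: int) -> Tensor:
    d = pool_to_grid(x, grid)
    B, C = d.shape[0], d.shape[1]
    return d.reshape(B, C, -1).transpose(0, 2, 1)   # (B, g*g, C)


def forward_student_with_substitution(student: Backbone, images,
                                      teacher_blocks: list[np.ndarray],
                                      alphas) -> tuple:
    """Student forward where block k's input may be gated toward the adapted
    teacher feature of block k−1.  Returns (pyramid, student block features).

    ``alphas`` holds per-block gate values — floats, or Tensors when the
    gates are trained: the mix then backpropagates into the gate logits, so
    a gate whose substitution raises the loss closes itself (the adaptive
    α → 0 behaviour).
    """
    images = nn.as_tensor(images)
    x = student.stem(images)
    maps, feats = {}, []
    bi = 0
    for i, stage in enumerate(student.stages):
        stage_start = True
        for blk in stage:
            a = alphas[bi]
            a_val = float(np.asarray(a.data if isinstance(a, Tensor) else a).reshape(-1)[0])
            # the gate needs T_{k-1} and S_{k-1} at the same stride/width,
            # so the first block of each stage is never substituted
            if bi > 0 and not stage_start and a_val > 0.0:
                t_prev = Tensor(adapt_teacher_channels(teacher_blocks[bi - 1],
                                                       x.shape[1]))
                if isinstance(a, Tensor):
                    x = t_prev * a + x * (1.0 - a)
                else:
                    x = gate_mix(t_prev, x, a_val)
            x = blk(x)
            feats.append(x)
            bi += 1
            stage_start = False
        maps[student.config.teacher_stages[i].stride] = x
        if i < len(student.downsamples):
            x = student.downsamples[i](x)
    from .backbone import FeaturePyramid
    return FeaturePyramid(maps=maps, block_features=feats), feats


def distill_losses(teacher_blocks, student_blocks, state: DistillState):
    """Per-block alignment losses on pooled descriptors.

    Each squared substitution error is normalized by the teacher
    descriptor's energy, giving a scale-free relative error of order one —
    comparable across blocks and commensurate with the detection loss.
    """
    losses = []
    g = state.descriptor_grid
    for pair, tb, sb in zip(state.pairings, teacher_blocks, student_blocks):
        t_tok = _descriptor_tokens(nn.as_tensor(tb).detach(), g)
        s_tok = _descriptor_tokens(sb, g)
        mapped = map_student_feature(s_tok, pair.mapping)
        energy = float((t_tok.data ** 2).sum()) + 1e-9
        losses.append(block_loss(t_tok, mapped) * (1.0 / energy))
    return losses


def distill_step(batch, teacher, student, state: DistillState,
                 detection_loss_fn=None, epoch: int = 0, total_epochs: int = 1,
                 distill_weight: float = 1.0):
    """One distillation step: frozen-teacher forward, substituted student
    forward, detection loss plus weighted per-block alignment losses.

    ``teacher``/``student`` are backbones; ``detection_loss_fn`` maps the
    student pyramid to a detection loss Tensor (optional — zero if absent).
    Returns (total loss Tensor, list of per-block loss values).
    """
    images = batch[0] if isinstance(batch, (tuple, list)) else batch
    if any(p.requires_grad for p in teacher.parameters()):
        raise ValueError("teacher must be frozen (no trainable parameters)")
    with nn.no_grad():
        t_pyr = teacher(nn.as_tensor(images))
    t_blocks = [f.data for f in t_pyr.block_features]
    bounds = schedule_alpha(epoch, total_epochs, state)
    alphas = np.array([p.gate_value(b) for p, b in zip(state.pairings, bounds)])
    active = set(state.active_blocks())
    alphas = np.array([a if i in active else 0.0 for i, a in enumerate(alphas)])
    s_pyr, s_blocks = forward_student_with_substitution(
        student, images, t_blocks, alphas)
    per_block = distill_losses(t_blocks, s_blocks, state)
    total = nn.Tensor(0.0)
    if detection_loss_fn is not None:
        total = total + detection_loss_fn(s_pyr)
    for w, l in zip(state.loss_weights, per_block):
        if w:
            total = total + l * (w * distill_weight)
    vals = [float(l.data) for l in per_block]
    state.update_running(vals)
    return total, vals
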