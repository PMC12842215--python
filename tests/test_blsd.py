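"""Block-level substitution distillation: mapping, loss, gating, schedule
and the closed-form parameter count of the substitution path."""

import numpy as np
import pytest

from pestlite import nn
from pestlite.backbone import BackboneConfig, build_backbone
from pestlite.blsd import (DistillState, SubstitutionBlock,
                           adapt_teacher_channels, block_loss, distill_step,
                           gate_mix, map_student_feature, schedule_alpha,
                           substitution_block_params)

rng = np.random.default_rng(0)


def _backbones():
    cfg = BackboneConfig()
    with nn.init_rng(3):
        teacher = build_backbone(cfg, "teacher")
        student = build_backbone(cfg, "student")
    return teacher, student


# ---------------------------------------------------------------------------
# map_student_feature / block_loss
# ---------------------------------------------------------------------------

def test_identity_mapping_preserves_features():
    s = rng.normal(size=(6, 4))
    assert np.array_equal(map_student_feature(s, np.eye(4)).data, s)


def test_mapping_is_linear_in_features():
    m = rng.normal(size=(4, 8))
    assert not map_student_feature(np.zeros((5, 4)), m).data.any()


def test_hand_computed_toy_mapping():
    s = np.array([[1.0, 0.0], [0.0, 1.0]])
    m = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    assert np.array_equal(map_student_feature(s, m).data, m)


def test_mapping_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="width"):
        map_student_feature(np.zeros((2, 3)), np.eye(4))


def test_block_loss_zero_iff_equal():
    t = rng.normal(size=(3, 4))
    assert block_loss(t, t).data == 0.0
    assert block_loss(t, t + 1e-3).data > 0.0


def test_block_loss_sums_squares():
    t = np.zeros((2, 3))
    assert block_loss(t, t + 1.0).data == pytest.approx(6.0)


def test_block_loss_matches_least_squares_residual():
    """With the optimal M from the normal equations, the substitution error
    equals the least-squares residual."""
    s = rng.normal(size=(20, 4))
    t = rng.normal(size=(20, 8))
    m_opt, res, *_ = np.linalg.lstsq(s, t, rcond=None)
    loss = block_loss(t, map_student_feature(s, m_opt)).data
    assert loss == pytest.approx(res.sum(), rel=1e-10)


# ---------------------------------------------------------------------------
# gate_mix / schedule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("alpha,expect", [(0.0, "s"), (1.0, "t")])
def test_gate_endpoints(alpha, expect):
    t = rng.normal(size=(2, 3))
    s = rng.normal(size=(2, 3))
    z = gate_mix(t, s, alpha).data
    assert np.array_equal(z, t if expect == "t" else s)


def test_gate_energy_identity_exact():
    """||Z−S|| = α||T−S|| holds algebraically for every α."""
    t = np.array([2.0, 0.0])
    s = np.array([0.0, 2.0])
    z = gate_mix(t, s, 0.5).data
    assert np.array_equal(z, np.array([1.0, 1.0]))
    for alpha in np.linspace(0, 1, 11):
        z = gate_mix(t, s, alpha).data
        assert np.linalg.norm(z - s) == pytest.approx(
            alpha * np.linalg.norm(t - s), abs=1e-12)


def test_gate_clamps_out_of_range_with_warning():
    t, s = np.ones(3), np.zeros(3)
    with pytest.warns(UserWarning, match="clamped"):
        z = gate_mix(t, s, 1.5).data
    assert np.array_equal(z, t)


def test_schedule_linear_decay_reaches_zero_at_half():
    teacher, student = _backbones()
    state = DistillState(teacher, student)
    total = 20
    assert schedule_alpha(0, total, state)[0] == pytest.approx(1.0)
    assert schedule_alpha(5, total, state)[0] == pytest.approx(0.5)
    for e in range(10, total):
        assert schedule_alpha(e, total, state)[0] == 0.0
    assert np.all(np.diff([schedule_alpha(e, total, state)[0]
                           for e in range(total)]) <= 0)


def test_channel_adapter_is_group_mean():
    t = rng.normal(size=(1, 4, 2, 2))
    a = adapt_teacher_channels(t, 2)
    assert np.allclose(a[0, 0], t[0, :2].mean(axis=0))
    with pytest.raises(ValueError, match="divisible"):
        adapt_teacher_channels(t, 3)


# ---------------------------------------------------------------------------
# substitution block parameters
# ---------------------------------------------------------------------------

def test_substitution_params_closed_form():
    assert substitution_block_params(32, 4, 64) == 12288
    assert substitution_block_params(1, 1, 1) == 2


def test_substitution_params_match_instantiated_block():
    with nn.init_rng(0):
        blk = SubstitutionBlock(32, 64, expansion=4)
    linear_params = blk.fc1.weight.size + blk.fc2.weight.size
    assert linear_params == substitution_block_params(32, 4, 64)


# ---------------------------------------------------------------------------
# distill_step
# ---------------------------------------------------------------------------

def test_distill_step_requires_frozen_teacher():
    teacher, student = _backbones()
    state = DistillState(teacher, student)
    x = np.zeros((1, 3, 64, 64))
    with pytest.raises(ValueError, match="frozen"):
        distill_step((x,), teacher, student, state)


def test_distill_step_zero_weights_reduce_to_detection_loss():
    teacher, student = _backbones()
    teacher.requires_grad_(False)
    state = DistillState(teacher, student,
                         loss_weights=np.zeros(12))
    x = np.random.default_rng(1).normal(size=(1, 3, 64, 64))
    marker = 7.25
    total, per_block = distill_step(
        (x,), teacher, student, state,
        detection_loss_fn=lambda pyr: nn.Tensor(marker))
    assert total.data == pytest.approx(marker)
    assert len(per_block) == 12 and all(v >= 0 for v in per_block)


def test_distill_step_deterministic_and_teacher_untouched():
    teacher, student = _backbones()
    teacher.requires_grad_(False)
    before = {k: v.copy() for k, v in teacher.state_dict().items()}
    x = np.random.default_rng(2).normal(size=(1, 3, 64, 64))
    vals = []
    for _ in range(2):
        with nn.init_rng(5):
            state = DistillState(teacher, student)
        _, per_block = distill_step((x,), teacher, student, state)
        vals.append(per_block)
    assert vals[0] == vals[1]
    after = teacher.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_active_blocks_are_top_m_by_running_loss():
    teacher, student = _backbones()
    state = DistillState(teacher, student, top_m=4)
    state.running_loss = np.arange(12.0)
    assert state.active_blocks() == [8, 9, 10, 11]
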