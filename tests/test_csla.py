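"""Cross-scale lite attention: projections, pooled softmax attention,
low-rank factorization bounds, residual stability and linear complexity."""

import warnings

import numpy as np
import pytest

from pestlite import nn
from pestlite.csla import (AttentionFactor, CslaBlock, CslaConfig, CslaLevel,
                           CslaStack, fit_factors, lowrank_factorize,
                           project_qkv, scale_attention)
from pestlite.profiler import profile_callable

rng = np.random.default_rng(0)


# ---------------------------------------------------------------------------
# project_qkv
# ---------------------------------------------------------------------------

def test_projection_compresses_width_by_ratio():
    cfg = CslaConfig(compression_ratio=4)
    assert cfg.compressed(64) == 16
    with pytest.raises(ValueError, match="divisible"):
        cfg.compressed(66)


def test_projection_shapes_zero_and_degenerate():
    w = rng.normal(size=(8, 2))
    q, k, v = project_qkv(np.zeros((8, 3, 3)), w, w, w)
    assert q.shape == (9, 2) and not q.any() and not k.any() and not v.any()
    q1, _, _ = project_qkv(rng.normal(size=(8, 1, 1)), w, w, w)
    assert q1.shape == (1, 2)


def test_projection_is_linear():
    w = rng.normal(size=(4, 2))
    x = rng.normal(size=(4, 2, 2))
    q2, _, _ = project_qkv(2.0 * x, w, w, w)
    q1, _, _ = project_qkv(x, w, w, w)
    assert np.allclose(q2, 2.0 * q1)


# ---------------------------------------------------------------------------
# scale_attention
# ---------------------------------------------------------------------------

def test_single_token_attention_weight_is_one():
    q = rng.normal(size=(1, 4))
    out, attn = scale_attention(q, q, q)
    assert attn.shape == (1, 1) and attn[0, 0] == pytest.approx(1.0)
    assert np.allclose(out, q)


def test_identical_keys_give_uniform_attention():
    q = rng.normal(size=(5, 4))
    k = np.tile(rng.normal(size=(1, 4)), (6, 1))
    v = rng.normal(size=(6, 4))
    _, attn = scale_attention(q, k, v)
    assert np.allclose(attn, 1.0 / 6.0)


def test_attention_rows_normalize():
    q, k, v = (rng.normal(size=(12, 6)) for _ in range(3))
    _, attn = scale_attention(q, k, v, d_s=6)
    assert np.abs(attn.sum(axis=1) - 1.0).max() < 1e-6


def test_pooled_attention_token_counts():
    q = rng.normal(size=(16, 4))
    out, attn = scale_attention(q, q, q, s=2, spatial=(4, 4))
    assert attn.shape == (4, 4) and out.shape == (4, 4)


def test_empty_token_set_rejected():
    with pytest.raises(ValueError, match="empty|small"):
        scale_attention(np.zeros((2, 4)), np.zeros((2, 4)), np.zeros((2, 4)),
                        s=4, spatial=(2, 1))


# ---------------------------------------------------------------------------
# low-rank factorization (Eckart–Young machinery)
# ---------------------------------------------------------------------------

def test_rank1_matrix_factorizes_exactly():
    a = np.outer(rng.normal(size=5), rng.normal(size=7))
    f = lowrank_factorize(a, 1)
    assert np.linalg.norm(a - f.reconstruct()) < 1e-10
    assert f.error_bound() < 1e-10


def test_identity_truncation_error_closed_form():
    f = lowrank_factorize(np.eye(4), 2)
    err = np.linalg.norm(np.eye(4) - f.reconstruct())
    assert err == pytest.approx(np.sqrt(2.0), abs=1e-12)
    assert f.error_bound() == pytest.approx(2.0, abs=1e-12)


def test_random_matrix_error_bounded_by_singular_tail():
    a = np.random.default_rng(7).normal(size=(8, 8))
    f = lowrank_factorize(a, 4)
    s = np.linalg.svd(a, compute_uv=False)
    err = np.linalg.norm(a - f.reconstruct())
    assert err <= s[4:].sum() + 1e-12
    # the truncated SVD is also optimal: no learned factor beats it
    learned = fit_factors(a, 4, steps=300, seed=1)
    learned_err = np.linalg.norm(a - learned.reconstruct())
    assert err <= learned_err + 1e-9


def test_excessive_rank_warns():
    with pytest.warns(UserWarning, match="exact"):
        lowrank_factorize(np.eye(3), 5)


# ---------------------------------------------------------------------------
# csla_forward / modules
# ---------------------------------------------------------------------------

def _level(c=16, ratio=4, blocks=1, **kw):
    cfg = CslaConfig(compression_ratio=ratio, blocks_per_level=blocks,
                     level_dims=((4, c),), **kw)
    with nn.init_rng(0):
        return CslaLevel(4, c, cfg)


def test_zeroed_transform_is_exact_residual_identity():
    level = _level()
    for blk in level.blocks:
        blk.out.weight.data[:] = 0.0
    x = nn.Tensor(rng.normal(size=(1, 16, 8, 8)))
    y = level(x)
    assert np.array_equal(y.data, x.data)


@pytest.mark.parametrize("stride,c", [(4, 64), (8, 96), (16, 128)])
def test_levels_preserve_shape_at_teacher_widths(stride, c):
    cfg = CslaConfig()
    with nn.init_rng(0):
        stack = CslaStack(cfg)
    hw = 64 // (stride // 4)
    maps = {4: nn.Tensor(np.zeros((1, 64, 64, 64))),
            8: nn.Tensor(np.zeros((1, 96, 32, 32))),
            16: nn.Tensor(np.zeros((1, 128, 16, 16))),
            32: nn.Tensor(np.zeros((1, 192, 8, 8)))}
    out = stack(maps)
    assert out[stride].shape == maps[stride].shape


def test_shape_mismatch_names_level():
    level = _level(c=16)
    with pytest.raises(ValueError, match="stride 4"):
        level(nn.Tensor(np.zeros((1, 12, 8, 8))))


def test_gradients_survive_twelve_stacked_blocks():
    """Residual stability: the probe gradient neither vanishes nor explodes."""
    level = _level(c=16, blocks=12)
    x = nn.Tensor(rng.normal(size=(1, 16, 8, 8)), requires_grad=True)
    level(x).sum().backward()
    norm = np.linalg.norm(x.grad)
    ref = np.linalg.norm(np.ones(x.size))          # gradient of sum at identity
    assert 1e-2 * ref < norm < 1e3 * ref


def test_factorized_path_cost_linear_in_tokens():
    """MAC count of the factorized attention grows ~linearly with HW."""
    counts = []
    for hw in (32, 64):
        level = _level(c=16)
        x = nn.Tensor(np.zeros((1, 16, hw, hw)))
        counts.append(profile_callable(level, x)["total"])
    ratio = counts[1] / counts[0]
    assert ratio == pytest.approx(4.0, rel=0.15)


def test_explicit_attention_refuses_large_token_grids():
    level = _level(c=16, explicit_attention=True, materialize_threshold=64)
    with pytest.raises(RuntimeError, match="refused"):
        level(nn.Tensor(np.zeros((1, 16, 16, 16))))


def test_explicit_and_factorized_modes_share_shapes():
    x = rng.normal(size=(1, 16, 8, 8))
    for explicit in (False, True):
        level = _level(c=16, explicit_attention=explicit,
                       materialize_threshold=256)
        assert level(nn.Tensor(x)).shape == x.shape
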