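"""Feature fusion: epoch schedule, cross-branch attention vs oracle, SE gate."""

import math

import numpy as np
import pytest

from leafsam import nn
from leafsam import tensor as T
from leafsam.fusion import (CrossBranchAttention, Ffm, SeGate, alpha_epoch,
                            dense_attention_oracle)


@pytest.fixture(autouse=True)
def _seed():
    nn.seed_all(1)


# -- alpha schedule ----------------------------------------------------

def test_alpha_epoch_values():
    assert alpha_epoch(0, 0.2) == 0.0
    assert abs(alpha_epoch(10, 0.2) - (1 - math.exp(-2))) < 1e-12
    assert abs(alpha_epoch(10, 0.2) - 0.864665) < 1e-6


def test_alpha_epoch_monotone_bounded():
    vals = [alpha_epoch(e, 0.2) for e in range(201)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert vals[-1] <= 1.0
    # strict increase of alpha = strict decrease of exp(-beta*e); the decay
    # factor stays representable long after 1 - exp(-beta*e) rounds to 1.0
    decay = [math.exp(-0.2 * e) for e in range(201)]
    assert all(b < a for a, b in zip(decay, decay[1:]))
    assert all(b > a for a, b in zip(vals[:150], vals[1:150]))


def test_alpha_epoch_validation():
    with pytest.raises(ValueError):
        alpha_epoch(-1, 0.2)
    with pytest.raises(ValueError):
        alpha_epoch(3, 0.0)


# -- cross-branch attention --------------------------------------------

def test_cba_matches_dense_oracle(rng):
    """Multi-head CBA equals a loop-based dense attention on 6x4 tokens."""
    cba = CrossBranchAttention(embed_dim=4, num_heads=2)
    fg = rng.standard_normal((6, 4))
    fl = rng.standard_normal((5, 4))
    ours = cba(T.Tensor(fg[None]), T.Tensor(fl[None])).data[0]
    ref = dense_attention_oracle(
        fg, fl, cba.w_q.weight.data, cba.w_k.weight.data, cba.w_v.weight.data,
        cba.w_q.bias.data, cba.w_k.bias.data, cba.w_v.bias.data, num_heads=2)
    assert np.abs(ours - ref).max() < 1e-6


def test_cba_reduces_to_self_attention_with_identity_projections(rng):
    cba = CrossBranchAttention(embed_dim=4, num_heads=1)
    for lin in (cba.w_q, cba.w_k, cba.w_v):
        lin.weight.data[...] = np.eye(4)
        lin.bias.data[...] = 0.0
    x = rng.standard_normal((1, 6, 4))
    out = cba(T.Tensor(x), T.Tensor(x)).data[0]
    # independent softmax(X X^T / sqrt(d)) X
    s = x[0] @ x[0].T / 2.0
    w = np.exp(s - s.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    assert np.abs(out - w @ x[0]).max() < 1e-10


def test_cba_attention_rows_sum_to_one(rng):
    cba = CrossBranchAttention(embed_dim=8, num_heads=2)
    fg = T.Tensor(rng.standard_normal((2, 5, 8)))
    fl = T.Tensor(rng.standard_normal((2, 7, 8)))
    out, attn = cba(fg, fl, return_weights=True)
    assert out.shape == (2, 5, 8)
    assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)


def test_cba_single_local_token_broadcasts_value(rng):
    cba = CrossBranchAttention(embed_dim=6, num_heads=2)
    fg = T.Tensor(rng.standard_normal((1, 4, 6)))
    fl_one = rng.standard_normal((1, 1, 6))
    out = cba(fg, T.Tensor(fl_one)).data
    v = cba.w_v(T.Tensor(fl_one)).data
    assert np.abs(out - v).max() < 1e-12


def test_cba_rejects_width_mismatch(rng):
    cba = CrossBranchAttention(embed_dim=8, num_heads=2)
    with pytest.raises(ValueError):
        cba(T.Tensor(rng.standard_normal((1, 4, 6))),
            T.Tensor(rng.standard_normal((1, 4, 6))))


# -- SE gate -----------------------------------------------------------

def test_se_gate_epoch_zero_halves_exactly(rng):
    se = SeGate(embed_dim=8, se_reduction=4, beta=0.2)
    x = T.Tensor(rng.standard_normal((2, 5, 8)))
    out = se(x, epoch=0).data
    assert np.abs(out - 0.5 * x.data).max() == 0.0


def test_se_gate_bounds_and_shape(rng):
    se = SeGate(embed_dim=8, se_reduction=4, beta=0.2)
    x = T.Tensor(rng.standard_normal((2, 5, 8)))
    g = se.gate(x, epoch=50).data
    assert g.shape == (2, 1, 8)          # one gate per channel, all tokens
    assert (g > 0).all() and (g < 1).all()


# -- full module -------------------------------------------------------

def test_ffm_identity_fallback_exact(rng):
    ffm = Ffm(embed_dim=8, num_heads=2, mode="identity")
    fg = T.Tensor(rng.standard_normal((1, 4, 8)))
    fl = T.Tensor(rng.standard_normal((1, 9, 8)))
    out = ffm(fg, fl, epoch=3)
    assert np.array_equal(out.data, fg.data)


def test_ffm_output_shape_and_residual(rng):
    ffm = Ffm(embed_dim=8, num_heads=2)
    fg = T.Tensor(rng.standard_normal((2, 4, 8)))
    fl = T.Tensor(rng.standard_normal((2, 6, 8)))
    out = ffm(fg, fl, epoch=0)
    assert out.shape == fg.shape
    nores = Ffm(embed_dim=8, num_heads=2, residual=False)
    nores.load_state_dict(ffm.state_dict())
    delta = nores(fg, fl, epoch=0).data
    assert np.abs((out.data - fg.data) - delta).max() < 1e-12


def test_ffm_distance_from_identity_grows_with_epoch(rng):
    """With positive pre-sigmoid SE activations, the gated branch's norm is
    non-decreasing in epoch (alpha monotone)."""
    ffm = Ffm(embed_dim=4, num_heads=1)
    # force positive SE activations
    ffm.se.fc1.weight.data[...] = 0.0
    ffm.se.fc1.bias.data[...] = 1.0
    ffm.se.fc2.weight.data[...] = 0.0
    ffm.se.fc2.bias.data[...] = 2.0
    fg = T.Tensor(rng.standard_normal((1, 5, 4)))
    fl = T.Tensor(rng.standard_normal((1, 5, 4)))
    norms = [float(np.linalg.norm(ffm(fg, fl, epoch=e).data - fg.data))
             for e in range(0, 60, 10)]
    assert all(b >= a - 1e-12 for a, b in zip(norms, norms[1:]))
    assert norms[-1] > norms[0]
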