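"""Dual-branch encoder: shapes, freezing, zero-start equivalence."""

import numpy as np
import pytest

import leafsam as ls
from leafsam import nn
from leafsam import tensor as T
from leafsam.config import model_config
from leafsam.encoder import ImageEncoder, Lfem

from conftest import backbone_twin


def _tiny_encoder(**overrides):
    nn.seed_all(0)
    return ImageEncoder(model_config("tiny", **overrides))


def test_patch_embed_token_counts(rng):
    enc = _tiny_encoder()
    x = T.Tensor(rng.random((1, 3, 64, 64)))
    tokens = enc.embed_patches(x)
    assert tokens.shape == (1, 64, 64)          # (64/8)^2 tokens of width 64
    tokens2 = enc.embed_patches(x)
    assert np.array_equal(tokens.data, tokens2.data)
    with pytest.raises(ValueError):
        enc.embed_patches(T.Tensor(rng.random((1, 3, 32, 32))))


def test_paper_patch_arithmetic():
    cfg = model_config("paper")
    assert cfg.grid_size == 16                  # 256/16 -> 256 tokens
    assert cfg.grid_size ** 2 == 256


def test_lfem_resolution_contract(rng):
    enc = _tiny_encoder()
    f_l, f_ln = enc.lfem(T.Tensor(rng.random((1, 3, 64, 64))))
    assert f_l.shape == (1, 32, 16, 16)         # 1/4 resolution
    assert f_ln.shape == (1, 64, 8, 8)          # token grid, embed_dim channels


def test_lfem_zero_propagation():
    """Fresh biases are zero, so an all-zero image maps to all-zero features."""
    nn.seed_all(0)
    lfem = Lfem(model_config("tiny"))
    f_l, f_ln = lfem(T.Tensor(np.zeros((1, 3, 64, 64))))
    assert np.abs(f_l.data).max() == 0.0
    assert np.abs(f_ln.data).max() == 0.0


def test_lfem_channel_schedule_validation():
    with pytest.raises(ValueError):
        Lfem(model_config("tiny", lfem_channel_schedule=(16, 32, 64)))


def test_vit_block_zero_start_equals_frozen_host(rng):
    """Zero-init adapters + identity FFM reproduce the frozen block exactly."""
    full, bare = backbone_twin(seed=2, ffm_mode="identity", fuse_lfem=False)
    x = T.Tensor(rng.standard_normal((1, 64, 64)))
    fl = T.Tensor(rng.standard_normal((1, 256, 64)))
    a = full.encoder.blocks[0](x, fl, epoch=0, grid_hw=(8, 8))
    b = bare.encoder.blocks[0](x, None, epoch=0, grid_hw=(8, 8))
    assert np.abs(a.data - b.data).max() < 1e-5
    assert a.shape == x.shape


def test_vit_block_rejects_negative_epoch(rng):
    enc = _tiny_encoder()
    x = T.Tensor(rng.standard_normal((1, 64, 64)))
    with pytest.raises(ValueError):
        enc.blocks[0](x, None, epoch=-1, grid_hw=(8, 8))


def test_encoder_output_shapes_tiny(rng):
    enc = _tiny_encoder()
    with T.no_grad():
        out = enc(T.Tensor(rng.random((2, 3, 64, 64))), epoch=0)
    assert out.shape == (2, 32, 8, 8)


def test_encoder_deterministic_in_eval(rng):
    enc = _tiny_encoder().eval()
    x = T.Tensor(rng.random((1, 3, 64, 64)))
    with T.no_grad():
        a = enc(x, epoch=1).data
        b = enc(x, epoch=1).data
    assert np.array_equal(a, b)


def test_full_encoder_zero_start_equivalence(rng):
    full, bare = backbone_twin(seed=5, ffm_mode="identity", fuse_lfem=False)
    x = T.Tensor(rng.random((2, 3, 64, 64)))
    with T.no_grad():
        a = full.encoder(x, epoch=0).data
        b = bare.encoder(x, epoch=0).data
    assert np.abs(a - b).max() < 1e-5


def test_frozen_gradient_audit(tiny_model, rng):
    """Frozen ViT parameters get exactly zero gradient; trainable groups train."""
    m = tiny_model
    x = rng.random((2, 3, 64, 64))
    mask = (rng.random((2, 64, 64)) > 0.7).astype(float)
    out = m(x, epoch=1)
    total, _ = ls.joint_loss(T.sigmoid(out.mask_logits), None, out.class_logits,
                             mask, np.array([0, 1]), ls.LossWeights())
    total.backward()
    for p in m.frozen_parameters():
        assert p.grad is None or np.abs(p.grad).max() == 0.0
    groups = {
        "adapters": [p for n, p in m.named_parameters() if ".maa" in n],
        "lfem": [p for n, p in m.named_parameters() if ".lfem." in n],
        "ffm": [p for n, p in m.named_parameters() if ".ffm." in n],
        "decoder": [p for n, p in m.named_parameters() if n.startswith("decoder.")],
    }
    for name, params in groups.items():
        assert params, name
        gmax = max(0.0 if p.grad is None else np.abs(p.grad).max() for p in params)
        assert gmax > 0.0, f"group {name} received no gradient"


def test_window_partition_roundtrip(rng):
    from leafsam.encoder import _window_partition, _window_unpartition
    x = T.Tensor(rng.standard_normal((2, 6, 6, 4)))
    win, pad_hw = _window_partition(x, 4)     # pads 6 -> 8, four windows
    assert win.shape == (2 * 4, 16, 4)
    back = _window_unpartition(win, 4, pad_hw, (6, 6))
    assert np.array_equal(back.data, x.data)


def test_paper_preset_encoder_output_shape(rng):
    """ViT-b dims: (256, 16, 16) embedding from a 256x256 image."""
    nn.seed_all(0)
    enc = ImageEncoder(model_config("paper"))
    with T.no_grad():
        out = enc(T.Tensor(rng.random((1, 3, 256, 256))), epoch=0)
    assert out.shape == (1, 256, 16, 16)
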