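"""Dual-branch image encoder.

The global branch (GFEM) is a SAM-style ViT whose blocks are frozen; each
block carries two trainable Multi-Scale Adaptive Adapters and a Feature
Fusion Module that conditions the attention input on the local branch.  The
local branch (LFEM) is a small trainable convolutional pyramid whose final
map matches the token grid; the two branches are summed before the SAM neck:

    F_out = F_G,N + F_L,N  ->  neck  ->  (neck_dim, grid, grid)

Block flow (N-th block, x = F_{G,N-1}):

    F_G = LN(x)
    A   = Attention(FFM(F_G, F_L, epoch))
    F'  = A + MAA1(A) + x
    out = MLP(LN(F')) + MAA2(LN(F')) + F'

The adapters contribute additively alongside the frozen sublayers, so with
their zero-initialised up-projections (and the FFM in identity mode, the
local-branch sum disabled) the encoder reproduces the frozen backbone
exactly.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from . import tensor as T
from .config import ModelConfig
from .fusion import Ffm
from .maa import Maa
from .tensor import Tensor, grid_to_tokens, tokens_to_grid


def _window_partition(x: Tensor, ws: int):
    """(N, H, W, D) -> (N*nWin, ws*ws, D) with zero padding, SAM convention."""
    n, h, w, d = x.shape
    ph, pw = (-h) % ws, (-w) % ws
    if ph or pw:
        x = T.transpose(T.pad2d(T.transpose(x, (0, 3, 1, 2)), ph, pw), (0, 2, 3, 1))
    hp, wp = h + ph, w + pw
    x = T.reshape(x, (n, hp // ws, ws, wp // ws, ws, d))
    x = T.transpose(x, (0, 1, 3, 2, 4, 5))
    return T.reshape(x, (n * (hp // ws) * (wp // ws), ws * ws, d)), (hp, wp)


def _window_unpartition(x: Tensor, ws: int, pad_hw, orig_hw) -> Tensor:
    hp, wp = pad_hw
    h, w = orig_hw
    b = x.shape[0] // ((hp // ws) * (wp // ws))
    d = x.shape[-1]
    x = T.reshape(x, (b, hp // ws, wp // ws, ws, ws, d))
    x = T.transpose(x, (0, 1, 3, 2, 4, 5))
    x = T.reshape(x, (b, hp, wp, d))
    if hp > h or wp > w:
        x = x[:, :h, :w, :]
    return x


class Attention(nn.Module):
    """Standard multi-head self-attention (qkv + output projection)."""

    def __init__(self, dim: int, num_heads: int):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.qkv = nn.Linear(dim, 3 * dim)
        self.proj = nn.Linear(dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        b, L, d = x.shape
        qkv = T.reshape(self.qkv(x), (b, L, 3, self.num_heads, self.head_dim))
        qkv = T.transpose(qkv, (2, 0, 3, 1, 4))      # (3, B, heads, L, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scale = 1.0 / math.sqrt(self.head_dim)
        attn = T.softmax(T.matmul(q, T.transpose(k, (0, 1, 3, 2))) * scale, axis=-1)
        out = T.matmul(attn, v)                      # (B, heads, L, hd)
        out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (b, L, d))
        return self.proj(out)


class ViTBlock(nn.Module):
    """Frozen ViT block hosting two adapters and a fusion module."""

    def __init__(self, cfg: ModelConfig, block_index: int):
        super().__init__()
        d = cfg.embed_dim
        self.ln1 = nn.LayerNorm(d)
        self.ln2 = nn.LayerNorm(d)
        self.attn = Attention(d, cfg.num_heads)
        self.mlp = nn.Mlp(d, int(d * cfg.mlp_ratio))
        self.window_size = 0 if block_index in cfg.global_attn_indices \
            else cfg.window_size
        self.use_adapters = cfg.enable_adapters
        if self.use_adapters:
            self.maa1 = Maa(d, cfg.adapter_reduction, cfg.pool_sizes)
            self.maa2 = Maa(d, cfg.adapter_reduction, cfg.pool_sizes)
        self.use_ffm = cfg.ffm_mode != "off"
        if self.use_ffm:
            self.ffm = Ffm(d, cfg.num_heads, cfg.se_reduction, cfg.ffm_beta,
                           residual=cfg.ffm_residual, mode=cfg.ffm_mode)

    def _attention(self, x: Tensor, grid_hw) -> Tensor:
        h, w = grid_hw
        if self.window_size == 0:
            return self.attn(x)
        n = x.shape[0]
        xg = T.reshape(x, (n, h, w, x.shape[-1]))
        win, pad_hw = _window_partition(xg, self.window_size)
        win = self.attn(win)
        xg = _window_unpartition(win, self.window_size, pad_hw, (h, w))
        return T.reshape(xg, (n, h * w, x.shape[-1]))

    def forward(self, x: Tensor, f_local, epoch: int, grid_hw) -> Tensor:
        if epoch < 0:
            raise ValueError("epoch must be >= 0")
        fg = self.ln1(x)
        if self.use_ffm and f_local is not None:
            fg = self.ffm(fg, f_local, epoch)
        a = self._attention(fg, grid_hw)
        if self.use_adapters:
            x = a + self.maa1(a, grid_hw) + x
        else:
            x = a + x
        h = self.ln2(x)
        if self.use_adapters:
            return self.mlp(h) + self.maa2(h, grid_hw) + x
        return self.mlp(h) + x


class Lfem(nn.Module):
    """Local Feature Extraction Module: a convolutional pyramid.

    Stage 1: 3x3 conv (BN+ReLU) and max-pool; stage 2 sums a standard and a
    dilated 3x3 conv, max-pools, and compresses channels with a 1x1 conv to
    give ``F_L`` at 1/4 input resolution; further max-pool/conv stages bring
    the map to the token-grid resolution, the last stage using 3x3 convs with
    layer normalisation and GELU and ``embed_dim`` channels (``F_LN``).
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        n_pools = int(round(math.log2(cfg.patch_size)))
        if 2 ** n_pools != cfg.patch_size or n_pools < 3:
            raise ValueError("patch_size must be a power of two >= 8")
        sched = tuple(cfg.lfem_channel_schedule)
        if len(sched) != n_pools - 1:
            raise ValueError(
                f"lfem_channel_schedule needs {n_pools - 1} widths for "
                f"patch size {cfg.patch_size}, got {len(sched)}")
        c1, c2 = sched[0], sched[1]
        self.conv1 = nn.Sequential(nn.Conv2d(3, c1, 3, padding=1),
                                   nn.BatchNorm2d(c1), nn.ReLU())
        self.conv2_std = nn.Sequential(nn.Conv2d(c1, 2 * c2, 3, padding=1),
                                       nn.BatchNorm2d(2 * c2), nn.ReLU())
        self.conv2_dil = nn.Sequential(nn.Conv2d(c1, 2 * c2, 3, padding=2, dilation=2),
                                       nn.BatchNorm2d(2 * c2), nn.ReLU())
        self.compress = nn.Sequential(nn.Conv2d(2 * c2, c2, 1),
                                      nn.BatchNorm2d(c2), nn.ReLU())
        mids = []
        prev = c2
        for c in sched[2:]:
            mids.append(nn.Sequential(nn.MaxPool2d(2),
                                      nn.Conv2d(prev, c, 3, padding=1),
                                      nn.BatchNorm2d(c), nn.ReLU()))
            prev = c
        self.mid_stages = nn.ModuleList(mids)
        d = cfg.embed_dim
        self.final = nn.Sequential(
            nn.MaxPool2d(2),
            nn.Conv2d(prev, d, 3, padding=1), nn.LayerNorm2d(d), nn.GELU(),
            nn.Conv2d(d, d, 3, padding=1), nn.LayerNorm2d(d), nn.GELU())
        self.local_channels = c2

    def forward(self, image: Tensor):
        x = T.maxpool2d(self.conv1(image), 2)
        x = self.conv2_std(x) + self.conv2_dil(x)
        f_l = self.compress(T.maxpool2d(x, 2))     # 1/4 resolution
        x = f_l
        for stage in self.mid_stages:
            x = stage(x)
        f_ln = self.final(x)                       # token-grid resolution
        return f_l, f_ln


class ImageEncoder(nn.Module):
    """GFEM + LFEM with FFM-conditioned blocks and a SAM-style neck."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        d, g = cfg.embed_dim, cfg.grid_size
        self.patch_embed = nn.PatchConv2d(3, d, cfg.patch_size)
        self.pos_embed = nn.Parameter(
            nn._RNG.normal(0.0, 0.02, size=(1, g * g, d)))
        self.blocks = nn.ModuleList(
            [ViTBlock(cfg, i) for i in range(cfg.depth)])
        self.lfem = Lfem(cfg)
        # project F_L to embed_dim and pool to the FFM key grid
        self.local_proj = nn.Conv2d(self.lfem.local_channels, d, 1)
        self.key_grid = min(cfg.ffm_key_scale * g, cfg.image_size // 4)
        self.neck = nn.Sequential(
            nn.Conv2d(d, cfg.neck_dim, 1, bias=False),
            nn.LayerNorm2d(cfg.neck_dim),
            nn.Conv2d(cfg.neck_dim, cfg.neck_dim, 3, padding=1, bias=False),
            nn.LayerNorm2d(cfg.neck_dim))
        if cfg.freeze_vit:
            self.apply_freezing()

    # -- freezing ------------------------------------------------------
    def frozen_submodules(self):
        mods = {"patch_embed": self.patch_embed, "neck": self.neck}
        for i, blk in enumerate(self.blocks):
            for name in ("ln1", "ln2", "attn", "mlp"):
                mods[f"blocks.{i}.{name}"] = getattr(blk, name)
        return mods

    def apply_freezing(self) -> None:
        for m in self.frozen_submodules().values():
            m.requires_grad_(False)
        self.pos_embed.requires_grad = False

    def frozen_parameters(self):
        for m in self.frozen_submodules().values():
            yield from m.parameters()
        yield self.pos_embed

    def trainable_parameters(self):
        frozen = {id(p) for p in self.frozen_parameters()}
        for p in self.parameters():
            if id(p) not in frozen:
                yield p

    # -- forward -------------------------------------------------------
    def embed_patches(self, image: Tensor) -> Tensor:
        if image.shape[-1] != self.cfg.image_size or image.shape[-2] != self.cfg.image_size:
            raise ValueError(
                f"expected {self.cfg.image_size}x{self.cfg.image_size} input, "
                f"got {image.shape[-2]}x{image.shape[-1]}")
        return grid_to_tokens(self.patch_embed(image)) + self.pos_embed

    def forward(self, image: Tensor, epoch: int = 0) -> Tensor:
        cfg = self.cfg
        g = cfg.grid_size
        f_local_tokens = None
        f_ln = None
        need_lfem = cfg.fuse_lfem or cfg.ffm_mode == "active"
        if need_lfem:
            f_l, f_ln = self.lfem(image)
            if cfg.ffm_mode == "active":
                keys = T.adaptive_avg_pool2d(self.local_proj(f_l), self.key_grid)
                f_local_tokens = grid_to_tokens(keys)
        x = self.embed_patches(image)
        for blk in self.blocks:
            x = blk(x, f_local_tokens, epoch, (g, g))
        fg_n = tokens_to_grid(x, g, g)
        if cfg.fuse_lfem:
            fg_n = fg_n + f_ln
        return self.neck(fg_n)
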