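"""Mask–class hybrid decoder.

A SAM-style mask decoder — learned output tokens attend to the image
embedding through a two-way transformer, a transposed-convolution head
upsamples the embedding 4x, and a hypernetwork MLP turns the mask token into
per-pixel logits — extended with a lightweight classification head (global
average pooling + two fully connected layers over the image embedding).  The
pipeline runs unprompted by default: an empty sparse token set and a learned
"no mask" dense embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from . import tensor as T
from .config import ModelConfig
from .tensor import Tensor, grid_to_tokens


@dataclass
class SegClassOutput:
    """Per-pixel mask logits, scalar mask-quality estimate, class logits."""
    mask_logits: Tensor          # (N, H, W) at input resolution
    iou_estimate: Tensor         # (N,) in [0, 1]
    class_logits: Tensor | None  # (N, num_classes)


class CrossAttention(nn.Module):
    """q/k/v-projected multi-head attention between two sequences."""

    def __init__(self, dim: int, num_heads: int):
        super().__init__()
        self.num_heads, self.head_dim = num_heads, dim // num_heads
        self.q_proj = nn.Linear(dim, dim)
        self.k_proj = nn.Linear(dim, dim)
        self.v_proj = nn.Linear(dim, dim)
        self.out_proj = nn.Linear(dim, dim)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        import math
        b, Lq, d = q.shape
        def split(x):
            return T.transpose(
                T.reshape(x, (b, x.shape[1], self.num_heads, self.head_dim)),
                (0, 2, 1, 3))
        qh, kh, vh = split(self.q_proj(q)), split(self.k_proj(k)), split(self.v_proj(v))
        scale = 1.0 / math.sqrt(self.head_dim)
        attn = T.softmax(T.matmul(qh, T.transpose(kh, (0, 1, 3, 2))) * scale, -1)
        out = T.matmul(attn, vh)
        out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (b, Lq, d))
        return self.out_proj(out)


class TwoWayBlock(nn.Module):
    """Token self-attention, token->image and image->token cross-attention."""

    def __init__(self, dim: int, num_heads: int, mlp_ratio: float = 2.0):
        super().__init__()
        self.self_attn = CrossAttention(dim, num_heads)
        self.norm1 = nn.LayerNorm(dim)
        self.cross_t2i = CrossAttention(dim, num_heads)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, int(dim * mlp_ratio))
        self.norm3 = nn.LayerNorm(dim)
        self.cross_i2t = CrossAttention(dim, num_heads)
        self.norm4 = nn.LayerNorm(dim)

    def forward(self, tokens: Tensor, image: Tensor):
        tokens = self.norm1(tokens + self.self_attn(tokens, tokens, tokens))
        tokens = self.norm2(tokens + self.cross_t2i(tokens, image, image))
        tokens = self.norm3(tokens + self.mlp(tokens))
        image = self.norm4(image + self.cross_i2t(image, tokens, tokens))
        return tokens, image


class HyperMlp(nn.Module):
    """Three-layer MLP (ReLU) used for the hypernetwork and quality heads."""

    def __init__(self, dim: int, hidden: int, out: int):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, hidden)
        self.fc3 = nn.Linear(hidden, out)

    def forward(self, x):
        return self.fc3(T.relu(self.fc2(T.relu(self.fc1(x)))))


class MaskClassDecoder(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        d, g = cfg.neck_dim, cfg.grid_size
        rng = nn._RNG
        self.iou_token = nn.Parameter(rng.normal(0, 0.02, size=(1, 1, d)))
        self.mask_token = nn.Parameter(rng.normal(0, 0.02, size=(1, 1, d)))
        self.no_mask_embed = nn.Parameter(np.zeros((1, d, 1, 1)))
        self.image_pe = nn.Parameter(rng.normal(0, 0.02, size=(1, d, g, g)))
        self.blocks = nn.ModuleList(
            [TwoWayBlock(d, cfg.decoder_heads) for _ in range(cfg.decoder_depth)])
        self.final_attn = CrossAttention(d, cfg.decoder_heads)
        self.final_norm = nn.LayerNorm(d)
        self.upscale1 = nn.ConvTranspose2d(d, d // 4, 2)
        self.upnorm = nn.LayerNorm2d(d // 4)
        self.upscale2 = nn.ConvTranspose2d(d // 4, d // 8, 2)
        self.hyper = HyperMlp(d, d, d // 8)
        self.iou_head = HyperMlp(d, d, 1)
        self.cls_fc1 = nn.Linear(d, cfg.cls_hidden)
        self.cls_fc2 = nn.Linear(cfg.cls_hidden, cfg.num_classes)

    # -- prompts -------------------------------------------------------
    def default_prompt_embeddings(self, batch: int = 1):
        """Unprompted pathway: no sparse tokens, learned no-mask dense map."""
        g, d = self.cfg.grid_size, self.cfg.neck_dim
        sparse = T.as_tensor(np.zeros((batch, 0, d)))
        dense = self.no_mask_embed * T.as_tensor(np.ones((batch, d, g, g)))
        return sparse, dense

    # -- heads ---------------------------------------------------------
    def decode_masks(self, image_embedding: Tensor, sparse=None, dense=None):
        cfg = self.cfg
        n, d, g, g2 = image_embedding.shape
        if d != cfg.neck_dim or g != cfg.grid_size or g2 != cfg.grid_size:
            raise ValueError("image embedding shape does not match config")
        if sparse is None or dense is None:
            sparse, dense = self.default_prompt_embeddings(n)
        ones = T.as_tensor(np.ones((n, 1, 1)))
        tokens = T.concat([self.iou_token * ones, self.mask_token * ones], axis=1)
        if sparse.shape[1]:
            tokens = T.concat([tokens, sparse], axis=1)
        image = grid_to_tokens(image_embedding + dense + self.image_pe)
        for blk in self.blocks:
            tokens, image = blk(tokens, image)
        tokens = self.final_norm(tokens + self.final_attn(tokens, image, image))
        iou_tok, mask_tok = tokens[:, 0], tokens[:, 1]
        img = T.transpose(T.reshape(image, (n, g, g, d)), (0, 3, 1, 2))
        up = T.gelu(self.upnorm(self.upscale1(img)))
        up = T.gelu(self.upscale2(up))                     # (N, d/8, 4g, 4g)
        hyper = self.hyper(mask_tok)                       # (N, d/8)
        low = T.tsum(T.reshape(hyper, (n, d // 8, 1, 1)) * up, axis=1)
        low = T.reshape(low, (n, 1, 4 * g, 4 * g))
        mask = T.upsample_bilinear(low, cfg.image_size)
        mask = T.reshape(mask, (n, cfg.image_size, cfg.image_size))
        iou = T.sigmoid(T.reshape(self.iou_head(iou_tok), (n,)))
        return SegClassOutput(mask_logits=mask, iou_estimate=iou, class_logits=None)

    def classify(self, image_embedding: Tensor) -> Tensor:
        """GAP over the spatial grid, then two fully connected layers."""
        pooled = T.tmean(image_embedding, axis=(2, 3))
        return self.cls_fc2(T.relu(self.cls_fc1(pooled)))

    def forward(self, image_embedding: Tensor) -> SegClassOutput:
        out = self.decode_masks(image_embedding)
        out.class_logits = self.classify(image_embedding)
        return out
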