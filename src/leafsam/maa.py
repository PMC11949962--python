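"""Multi-Scale Adaptive Adapter (MAA).

A bottleneck adapter — down-projection, ReLU, a Multi-Scale Pyramid Feature
Module (MSPM) operating on the reshaped token grid, and a zero-initialised
up-projection — inserted twice per ViT block as the only trainable encoder
parameters besides the local branch and the fusion module.  The MSPM splits
the bottleneck channels into four groups, adaptively average-pools each group
to a pyramid scale, gates it with a content-dependent sigmoid weight, refines
it with a 1x1 + depthwise-separable convolution (GELU), restores resolution by
bilinear interpolation, and fuses the branches with an untouched trunk path
through a 1x1 convolution.

Because the up-projection starts at zero, the adapter's output is exactly
zero at initialisation and inserting it leaves the host network's function
unchanged until training moves the weights.
"""

from __future__ import annotations

import numpy as np

from . import nn
from . import tensor as T
from .tensor import Tensor, grid_to_tokens, tokens_to_grid


class DynamicScaleGate(nn.Module):
    """Per-branch 1x1 convolution + sigmoid producing gates in (0, 1)."""

    def __init__(self, channels: int):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 1)

    def forward(self, pooled: Tensor) -> Tensor:
        return T.sigmoid(self.conv(pooled))


class Mspm(nn.Module):
    """Multi-Scale Pyramid Feature Module on a C x H x W bottleneck grid."""

    def __init__(self, channels: int, pool_sizes=(1, 2, 3, 6),
                 activation: str = "gelu"):
        super().__init__()
        if channels % len(pool_sizes):
            raise ValueError(
                f"bottleneck channels ({channels}) must divide into "
                f"{len(pool_sizes)} pyramid branches")
        self.pool_sizes = tuple(pool_sizes)
        self.group_ch = channels // len(pool_sizes)
        self.channels = channels
        self.activation = activation
        self.gates = nn.ModuleList(
            [DynamicScaleGate(self.group_ch) for _ in pool_sizes])
        # C1: 1x1 conv then 3x3 depthwise-separable conv, per branch
        self.branch_conv1x1 = nn.ModuleList(
            [nn.Conv2d(self.group_ch, self.group_ch, 1) for _ in pool_sizes])
        self.branch_dwconv = nn.ModuleList(
            [nn.DepthwiseSeparableConv2d(self.group_ch, self.group_ch)
             for _ in pool_sizes])
        # C2: trunk 3x3 depthwise-separable conv on the ungrouped input
        self.trunk_conv = nn.DepthwiseSeparableConv2d(channels, channels)
        # C3: 1x1 fusion of concat(branches, trunk) = 2C -> C
        self.fuse_conv = nn.Conv2d(2 * channels, channels, 1)

    def _act(self, x: Tensor) -> Tensor:
        return T.gelu(x) if self.activation == "gelu" else x

    def forward(self, grid: Tensor, gate_override: float | None = None) -> Tensor:
        n, c, h, w = grid.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        if h < max(self.pool_sizes) or w < max(self.pool_sizes):
            raise ValueError("grid smaller than the largest pyramid scale")
        outs = []
        for j, p in enumerate(self.pool_sizes):
            group = grid[:, j * self.group_ch:(j + 1) * self.group_ch]
            pooled = T.adaptive_avg_pool2d(group, p)
            if gate_override is None:
                gate = self.gates[j](pooled)
            else:
                gate = T.as_tensor(np.full(pooled.shape, gate_override))
            gated = pooled * gate
            refined = self._act(self.branch_dwconv[j](self.branch_conv1x1[j](gated)))
            outs.append(T.upsample_bilinear(refined, (h, w)))
        trunk = self._act(self.trunk_conv(grid))
        return self.fuse_conv(T.concat(outs + [trunk], axis=1))

    def pooled_branch(self, grid: Tensor, j: int) -> Tensor:
        """Pre-gate pooled features of branch ``j`` (inspection helper)."""
        group = grid[:, j * self.group_ch:(j + 1) * self.group_ch]
        return T.adaptive_avg_pool2d(group, self.pool_sizes[j])


class Maa(nn.Module):
    """Bottleneck adapter whose middle stage is the MSPM.

    ``forward`` returns the adapter *delta* only; the host block adds it to
    its own residual stream.  ``activation='identity'`` disables the ReLU and
    the MSPM's GELUs, turning the adapter into a linear map (used to verify
    linearity in tests).
    """

    def __init__(self, embed_dim: int, reduction: int = 4,
                 pool_sizes=(1, 2, 3, 6), activation: str = "relu"):
        super().__init__()
        if embed_dim % reduction:
            raise ValueError("embed_dim must be divisible by reduction")
        mid = embed_dim // reduction
        self.embed_dim, self.mid = embed_dim, mid
        self.activation = activation
        self.down = nn.Linear(embed_dim, mid)
        self.mspm = Mspm(mid, pool_sizes,
                         activation="gelu" if activation == "relu" else "identity")
        self.up = nn.Linear(mid, embed_dim, zero_init=True)

    def forward(self, tokens: Tensor, grid_hw: tuple[int, int],
                gate_override: float | None = None) -> Tensor:
        n, L, d = tokens.shape
        h, w = grid_hw
        if L != h * w:
            raise ValueError(f"token count {L} is not a {h}x{w} grid")
        if d != self.embed_dim:
            raise ValueError(f"expected width {self.embed_dim}, got {d}")
        x = self.down(tokens)
        if self.activation == "relu":
            x = T.relu(x)
        g = tokens_to_grid(x, h, w)
        g = self.mspm(g, gate_override=gate_override)
        return self.up(grid_to_tokens(g))
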