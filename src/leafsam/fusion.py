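"""Feature Fusion Module (FFM).

Cross-Branch Attention (CBA) takes its queries from the global (ViT) branch
and its keys/values from the local (convolutional) branch, then a
Squeeze-and-Excitation gate rescales channels with a strength that grows over
training epochs through the coefficient

    alpha_epoch = 1 - exp(-beta * epoch),

so the local branch's influence ramps up smoothly from zero.  The fused
branch is added residually to the global tokens (configurable to the literal
non-residual form); an ``identity`` mode bypasses fusion entirely, which
keeps the host network's function intact and is used by the zero-start
checks.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from . import tensor as T
from .tensor import Tensor


def alpha_epoch(epoch: int, beta: float) -> float:
    """Epoch-scheduled SE strength: ``1 - exp(-beta * epoch)`` in [0, 1)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return 1.0 - math.exp(-beta * epoch)


class CrossBranchAttention(nn.Module):
    """Multi-head attention with global queries and local keys/values.

    Key/value token count may differ from the query count; output length
    always equals the query length.  Per the published formulation there is
    no output projection — the weighted values are concatenated across heads.
    """

    def __init__(self, embed_dim: int, num_heads: int):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError("embed_dim must be divisible by num_heads")
        self.embed_dim, self.num_heads = embed_dim, num_heads
        self.head_dim = embed_dim // num_heads
        self.w_q = nn.Linear(embed_dim, embed_dim)
        self.w_k = nn.Linear(embed_dim, embed_dim)
        self.w_v = nn.Linear(embed_dim, embed_dim)

    def _split(self, x: Tensor) -> Tensor:
        n, L, d = x.shape
        return T.transpose(T.reshape(x, (n, L, self.num_heads, self.head_dim)),
                           (0, 2, 1, 3))

    def forward(self, f_global: Tensor, f_local: Tensor,
                return_weights: bool = False):
        if f_global.shape[-1] != self.embed_dim or f_local.shape[-1] != self.embed_dim:
            raise ValueError("token width must equal embed_dim")
        q = self._split(self.w_q(f_global))
        k = self._split(self.w_k(f_local))
        v = self._split(self.w_v(f_local))
        scale = 1.0 / math.sqrt(self.head_dim)
        attn = T.softmax(T.matmul(q, T.transpose(k, (0, 1, 3, 2))) * scale, axis=-1)
        out = T.matmul(attn, v)
        n, _, Lq, _ = out.shape
        out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (n, Lq, self.embed_dim))
        if return_weights:
            return out, attn
        return out


class SeGate(nn.Module):
    """Channel gate ``sigmoid(W2 ReLU(W1 z) * alpha_epoch)`` applied per channel.

    ``z`` is the channel-wise mean over tokens; at epoch 0 the gate is exactly
    ``sigmoid(0) = 0.5`` on every channel.
    """

    def __init__(self, embed_dim: int, se_reduction: int = 16, beta: float = 0.2):
        super().__init__()
        hidden = max(1, embed_dim // se_reduction)
        self.fc1 = nn.Linear(embed_dim, hidden)
        self.fc2 = nn.Linear(hidden, embed_dim)
        self.beta = beta

    def gate(self, features: Tensor, epoch: int) -> Tensor:
        z = T.tmean(features, axis=1)            # (N, D)
        a = alpha_epoch(epoch, self.beta)
        s = T.sigmoid(self.fc2(T.relu(self.fc1(z))) * a)
        n, d = s.shape
        return T.reshape(s, (n, 1, d))

    def forward(self, features: Tensor, epoch: int) -> Tensor:
        return features * self.gate(features, epoch)


class Ffm(nn.Module):
    """Cross-branch attention + epoch-scheduled SE gating.

    ``mode='identity'`` returns the global tokens untouched (zero-start
    fallback); ``residual=False`` gives the literal gated-attention output
    with no skip connection.
    """

    def __init__(self, embed_dim: int, num_heads: int, se_reduction: int = 16,
                 beta: float = 0.2, residual: bool = True, mode: str = "active"):
        super().__init__()
        self.cba = CrossBranchAttention(embed_dim, num_heads)
        self.se = SeGate(embed_dim, se_reduction, beta)
        self.residual = residual
        self.mode = mode

    def forward(self, f_global: Tensor, f_local: Tensor, epoch: int) -> Tensor:
        if self.mode == "identity":
            return f_global
        fused = self.se(self.cba(f_global, f_local), epoch)
        return f_global + fused if self.residual else fused


def dense_attention_oracle(fg: np.ndarray, fl: np.ndarray, wq: np.ndarray,
                           wk: np.ndarray, wv: np.ndarray, bq, bk, bv,
                           num_heads: int) -> np.ndarray:
    """Independent O(n^2) loop-based attention used as a cross-check in tests."""
    q = fg @ wq + bq
    k = fl @ wk + bk
    v = fl @ wv + bv
    d = q.shape[-1] // num_heads
    out = np.zeros_like(q[..., : num_heads * d])
    for h in range(num_heads):
        qh, kh, vh = (m[..., h * d:(h + 1) * d] for m in (q, k, v))
        for i in range(qh.shape[0]):
            scores = np.array([qh[i] @ kh[j] / math.sqrt(d)
                               for j in range(kh.shape[0])])
            scores -= scores.max()
            w = np.exp(scores)
            w /= w.sum()
            out[i, h * d:(h + 1) * d] = sum(w[j] * vh[j] for j in range(kh.shape[0]))
    return out
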