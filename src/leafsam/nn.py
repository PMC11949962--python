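"""Neural-network layers over :mod:`leafsam.tensor`.

Follows the familiar Module/Parameter idiom: submodules and parameters are
registered through attribute assignment, ``state_dict``/``load_state_dict``
serialise to flat dicts of numpy arrays, and ``requires_grad_`` freezes or
thaws whole subtrees.  Layer initialisation draws from a process-wide seeded
generator (:func:`seed_all`) so model construction is reproducible.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Seed the generator used by all subsequent layer initialisations."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def _uniform(shape, bound):
    return _RNG.uniform(-bound, bound, size=shape)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        out.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, val in state.items():
            if key.startswith("buf:"):
                b = bufs[key[4:]]
                b[...] = val
            else:
                p = params[key]
                if p.data.shape != val.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data[...] = val

    # -- mode / freezing ----------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def requires_grad_(self, flag: bool = True):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self, trainable_only: bool = False) -> int:
        return sum(p.size for p in self.parameters()
                   if p.requires_grad or not trainable_only)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)


# ---------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------

class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 zero_init: bool = False):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        w = np.zeros((in_features, out_features)) if zero_init else \
            _uniform((in_features, out_features), bound)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = T.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """Stride-1 convolution (optionally grouped/dilated), NCHW."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int = 0,
                 dilation: int = 1, groups: int = 1, bias: bool = True):
        super().__init__()
        fan_in = in_ch // groups * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(_uniform((out_ch, in_ch // groups, kernel, kernel), bound))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.padding, self.dilation, self.groups = padding, dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.padding,
                        self.dilation, self.groups)


class PatchConv2d(Module):
    """Convolution with stride == kernel (patch embedding)."""

    def __init__(self, in_ch: int, out_ch: int, patch: int, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_ch * patch * patch)
        self.weight = Parameter(_uniform((out_ch, in_ch, patch, patch), bound))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d_patchify(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Transposed convolution with kernel == stride (upsampling head)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 2, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_ch)
        self.weight = Parameter(_uniform((in_ch, out_ch, stride, stride), bound))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2d(x, self.weight, self.bias, self.stride)


class DepthwiseSeparableConv2d(Module):
    """3x3 depthwise convolution followed by a pointwise 1x1 convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, bias: bool = True):
        super().__init__()
        self.depthwise = Conv2d(in_ch, in_ch, kernel, padding=kernel // 2,
                                groups=in_ch, bias=bias)
        self.pointwise = Conv2d(in_ch, out_ch, 1, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class LayerNorm(Module):
    """Normalisation over the last axis with learnable affine."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.normalize(x, (-1,), self.eps) * self.weight + self.bias


class LayerNorm2d(Module):
    """Channel normalisation of an NCHW map (SAM-neck style)."""

    def __init__(self, ch: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones((1, ch, 1, 1)))
        self.bias = Parameter(np.zeros((1, ch, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.normalize(x, (1,), self.eps) * self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones((1, ch, 1, 1)))
        self.bias = Parameter(np.zeros((1, ch, 1, 1)))
        self.register_buffer("running_mean", np.zeros(ch))
        self.register_buffer("running_var", np.ones(ch))
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var
            xhat = T.normalize(x, (0, 2, 3), self.eps)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            scale = (inv).reshape(1, -1, 1, 1)
            shift = (-self.running_mean * inv).reshape(1, -1, 1, 1)
            xhat = x * scale + shift
        return xhat * self.weight + self.bias


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class GELU(Module):
    def forward(self, x):
        return T.gelu(x)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return T.maxpool2d(x, self.k)


class Mlp(Module):
    """Transformer feed-forward block: Linear -> GELU -> Linear."""

    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)

    def forward(self, x):
        return self.fc2(T.gelu(self.fc1(x)))
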