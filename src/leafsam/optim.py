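"""Optimisers for the autograd engine."""

from __future__ import annotations

import numpy as np

from .nn import Parameter


class AdamW:
    """AdamW with decoupled weight decay.

    ``params`` may be a flat iterable of parameters or a list of groups
    ``{"params": [...], "weight_decay": float}``.  Only parameters with
    ``requires_grad`` set are accepted — feeding a frozen parameter raises,
    which is the audit hook used by the trainer.
    """

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        if params and isinstance(params[0], dict):
            groups = params
        else:
            groups = [{"params": list(params), "weight_decay": weight_decay}]
        self.groups = []
        for g in groups:
            plist = list(g["params"])
            for p in plist:
                if not isinstance(p, Parameter):
                    raise TypeError("optimizer expects Parameter instances")
                if not p.requires_grad:
                    raise ValueError("frozen parameter passed to optimizer")
            self.groups.append({
                "params": plist,
                "weight_decay": float(g.get("weight_decay", weight_decay)),
                "m": [np.zeros_like(p.data) for p in plist],
                "v": [np.zeros_like(p.data) for p in plist],
            })
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.t = 0

    @property
    def parameters(self):
        return [p for g in self.groups for p in g["params"]]

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for g in self.groups:
            wd = g["weight_decay"]
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                if p.grad is None:
                    continue
                m *= b1
                m += (1.0 - b1) * p.grad
                v *= b2
                v += (1.0 - b2) * p.grad ** 2
                if wd:
                    p.data *= 1.0 - self.lr * wd
                p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
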