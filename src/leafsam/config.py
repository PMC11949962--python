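"""Model and training configuration.

Two presets are provided: ``paper`` mirrors the published setup (SAM ViT-b
encoder, 256x256 inputs, patch 16, window 14, 26 classes) and ``tiny`` is a
CPU-scale configuration with the same topology used throughout the tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    # encoder / ViT branch
    image_size: int = 256
    patch_size: int = 16
    embed_dim: int = 768
    depth: int = 12
    num_heads: int = 12
    mlp_ratio: float = 4.0
    window_size: int = 14
    global_attn_indices: tuple = (2, 5, 8, 11)
    neck_dim: int = 256
    # local branch
    lfem_channel_schedule: tuple = (32, 64, 128)  # widths before embed_dim
    # adapters
    adapter_reduction: int = 4
    pool_sizes: tuple = (1, 2, 3, 6)
    enable_adapters: bool = True
    # feature fusion
    ffm_mode: str = "active"          # active | identity | off
    ffm_residual: bool = True
    se_reduction: int = 16
    ffm_beta: float = 0.2
    ffm_key_scale: int = 2            # local key grid = ffm_key_scale * token grid
    # encoder fusion (F_out = F_G,N + F_L,N)
    fuse_lfem: bool = True
    freeze_vit: bool = True
    # decoder
    decoder_depth: int = 2
    decoder_heads: int = 8
    num_classes: int = 26
    cls_hidden: int = 256

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.adapter_reduction:
            raise ValueError("embed_dim must be divisible by adapter_reduction")
        if (self.embed_dim // self.adapter_reduction) % len(self.pool_sizes):
            raise ValueError("bottleneck width must divide into pooling branches")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        grid = self.grid_size
        if max(self.pool_sizes) > grid:
            raise ValueError("pool sizes must not exceed the token grid")
        if self.ffm_mode not in ("active", "identity", "off"):
            raise ValueError(f"unknown ffm_mode {self.ffm_mode!r}")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def bottleneck_dim(self) -> int:
        return self.embed_dim // self.adapter_reduction

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kw[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)


PRESETS: dict[str, dict] = {
    # published setup: ViT-b dims, 256 px inputs, window 14, SAM neck 256
    "paper": dict(image_size=256, patch_size=16, embed_dim=768, depth=12,
                  num_heads=12, window_size=14, global_attn_indices=(2, 5, 8, 11),
                  neck_dim=256, lfem_channel_schedule=(32, 64, 128),
                  num_classes=26, cls_hidden=256, decoder_heads=8),
    # CPU-scale twin used by the tests
    "tiny": dict(image_size=64, patch_size=8, embed_dim=64, depth=4,
                 num_heads=2, window_size=4, global_attn_indices=(1, 3),
                 neck_dim=32, lfem_channel_schedule=(16, 32),
                 num_classes=26, cls_hidden=64, decoder_heads=2),
}


def model_config(preset: str = "paper", **overrides) -> ModelConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return ModelConfig(**kw)


@dataclass
class LossWeights:
    """Weights of the joint objective (best ablation row: 0.6/0.2/0.2)."""
    lambda_mask: float = 0.6
    lambda_iou: float = 0.2
    lambda_cls: float = 0.2
    alpha_dice: float = 0.5
    beta_bce: float = 0.5

    def __post_init__(self):
        for v in (self.lambda_mask, self.lambda_iou, self.lambda_cls,
                  self.alpha_dice, self.beta_bce):
            if v < 0:
                raise ValueError("loss weights must be nonnegative")
        if self.alpha_dice + self.beta_bce <= 0:
            raise ValueError("alpha_dice + beta_bce must be positive")


@dataclass
class TrainConfig:
    preset: str = "tiny"
    epochs: int = 200
    batch_size: int = 4
    lr0: float = 5e-4
    lr_decay_k: float | None = None   # default: ln(10)/total_steps
    weight_decay: float = 0.01
    ffm_beta: float = 0.2
    seed: int = 0
    loss: LossWeights = field(default_factory=LossWeights)
    num_classes: int = 26
    out_dir: str = "runs/leafsam"
    model_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.ffm_beta <= 0:
            raise ValueError("ffm_beta must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "loss" in d and isinstance(d["loss"], dict):
            d["loss"] = LossWeights(**d["loss"])
        kw = {f.name: d[f.name] for f in dataclasses.fields(cls) if f.name in d}
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)
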