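"""Full segmentation–classification model and checkpoint handling."""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import numpy as np

from . import nn
from . import tensor as T
from .config import ModelConfig, model_config
from .decoder import MaskClassDecoder, SegClassOutput
from .encoder import ImageEncoder
from .tensor import Tensor


class LeafSam(nn.Module):
    """Adapter-tuned SAM-style encoder + mask–class hybrid decoder."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.encoder = ImageEncoder(cfg)
        self.decoder = MaskClassDecoder(cfg)

    @classmethod
    def from_preset(cls, preset: str = "tiny", seed: int = 0, **overrides) -> "LeafSam":
        nn.seed_all(seed)
        return cls(model_config(preset, **overrides))

    def forward(self, images, epoch: int = 0) -> SegClassOutput:
        x = images if isinstance(images, Tensor) else T.as_tensor(images)
        if x.ndim == 3:
            x = T.reshape(x, (1,) + tuple(x.shape))
        embedding = self.encoder(x, epoch)
        out = self.decoder.decode_masks(embedding)
        out.class_logits = self.decoder.classify(embedding)
        return out

    # -- parameter groups ---------------------------------------------
    def frozen_parameters(self):
        if self.cfg.freeze_vit:
            yield from self.encoder.frozen_parameters()

    def trainable_parameters(self):
        frozen = {id(p) for p in self.frozen_parameters()}
        for p in self.parameters():
            if id(p) not in frozen:
                yield p

    def frozen_flags(self) -> dict[str, bool]:
        frozen = {id(p) for p in self.frozen_parameters()}
        return {name: id(p) in frozen for name, p in self.named_parameters()}

    # -- persistence ---------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {"config": self.cfg.to_dict(),
                "frozen": self.frozen_flags(), **(extra or {})}
        arrays = dict(self.state_dict())
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> tuple["LeafSam", dict]:
        with np.load(Path(path), allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(bytes(arrays.pop("__meta__")).decode())
        cfg = ModelConfig.from_dict(meta["config"])
        nn.seed_all(int(meta.get("seed", 0)))
        model = cls(cfg)
        model.load_state_dict(arrays)
        return model, meta

    def checkpoint_hash(self) -> str:
        """Deterministic digest of all parameter and buffer values."""
        h = hashlib.sha256()
        for name, arr in sorted(self.state_dict().items()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


# -- optional pretrained SAM ViT-b weights -----------------------------

_SAM_KEY_MAP = [
    ("image_encoder.patch_embed.proj.weight", "encoder.patch_embed.weight"),
    ("image_encoder.patch_embed.proj.bias", "encoder.patch_embed.bias"),
    ("image_encoder.neck.0.weight", "encoder.neck.0.weight"),
    ("image_encoder.neck.1.weight", "encoder.neck.1.weight"),
    ("image_encoder.neck.1.bias", "encoder.neck.1.bias"),
    ("image_encoder.neck.2.weight", "encoder.neck.2.weight"),
    ("image_encoder.neck.3.weight", "encoder.neck.3.weight"),
    ("image_encoder.neck.3.bias", "encoder.neck.3.bias"),
]


def load_sam_backbone(model: LeafSam, npz_path) -> list[str]:
    """Load frozen ViT-b backbone weights from a converted ``.npz`` archive.

    The archive uses the reference SAM checkpoint's key names (converted to
    numpy offline).  Matched frozen groups are overwritten; unmatched keys
    are reported and left at their fresh initialisation, so the model runs
    with or without the checkpoint.
    """
    with np.load(Path(npz_path)) as z:
        src = {k: z[k] for k in z.files}
    params = dict(model.named_parameters())
    missing = []

    def assign(dst_key, arr):
        p = params[dst_key]
        if dst_key.endswith("patch_embed.weight"):
            pass  # layout already (D, C, p, p)
        elif arr.ndim == 2 and p.data.shape == arr.T.shape:
            arr = arr.T  # reference Linear stores (out, in)
        elif arr.ndim == 1 and p.data.shape == (1, arr.size, 1, 1):
            arr = arr.reshape(1, -1, 1, 1)  # channel-norm affine
        if p.data.shape != arr.shape:
            raise ValueError(f"shape mismatch for {dst_key}: {p.data.shape} vs {arr.shape}")
        p.data[...] = arr

    keymap = dict(_SAM_KEY_MAP)
    for i in range(model.cfg.depth):
        pre = f"image_encoder.blocks.{i}."
        dst = f"encoder.blocks.{i}."
        keymap.update({
            pre + "norm1.weight": dst + "ln1.weight",
            pre + "norm1.bias": dst + "ln1.bias",
            pre + "norm2.weight": dst + "ln2.weight",
            pre + "norm2.bias": dst + "ln2.bias",
            pre + "attn.qkv.weight": dst + "attn.qkv.weight",
            pre + "attn.qkv.bias": dst + "attn.qkv.bias",
            pre + "attn.proj.weight": dst + "attn.proj.weight",
            pre + "attn.proj.bias": dst + "attn.proj.bias",
            pre + "mlp.lin1.weight": dst + "mlp.fc1.weight",
            pre + "mlp.lin1.bias": dst + "mlp.fc1.bias",
            pre + "mlp.lin2.weight": dst + "mlp.fc2.weight",
            pre + "mlp.lin2.bias": dst + "mlp.fc2.bias",
        })
    for src_key, dst_key in keymap.items():
        if src_key in src:
            arr = src[src_key]
            if dst_key.startswith("encoder.neck") and arr.ndim == 4:
                pass
            assign(dst_key, arr)
        else:
            missing.append(src_key)
    if "image_encoder.pos_embed" in src:
        pe = src["image_encoder.pos_embed"]  # (1, g, g, D)
        g = model.cfg.grid_size
        if pe.shape[1] == g:
            params_pe = dict(model.named_parameters())["encoder.pos_embed"]
            params_pe.data[...] = pe.reshape(1, g * g, -1)
    else:
        missing.append("image_encoder.pos_embed")
    return missing
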