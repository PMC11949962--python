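import numpy as np
import pytest

import leafsam as ls
from leafsam import tensor as T


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_model():
    return ls.LeafSam.from_preset("tiny", seed=0)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small synthetic dataset: 2 classes x 5 images, 64 px (8 train / 2 test)."""
    out = tmp_path_factory.mktemp("tinyds")
    spec = ls.SyntheticSpec(n_classes=2, images_per_class=5, image_size=64, seed=0)
    manifest = ls.generate_dataset(spec, out)
    return out, manifest, spec


def backbone_twin(seed: int, **overrides):
    """A frozen backbone-only model sharing weights with an adapter model.

    Returns (full, bare): ``full`` has zero-init adapters and whatever
    fusion flags ``overrides`` request; ``bare`` is the plain frozen ViT.
    """
    full = ls.LeafSam.from_preset("tiny", seed=seed, **overrides)
    bare = ls.LeafSam.from_preset("tiny", seed=seed, ffm_mode="off",
                                  fuse_lfem=False, enable_adapters=False)
    src = dict(full.named_parameters())
    for name, p in bare.named_parameters():
        if name in src:
            p.data[...] = src[name].data
    return full, bare


def finite_diff_grad(fn, x: np.ndarray, seed: np.ndarray, eps: float = 1e-6):
    """Central-difference gradient of sum(fn(x) * seed) w.r.t. x."""
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        f1 = float((fn(x).data * seed).sum())
        flat[i] = orig - eps
        f2 = float((fn(x).data * seed).sum())
        flat[i] = orig
        gf[i] = (f1 - f2) / (2 * eps)
    return g
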