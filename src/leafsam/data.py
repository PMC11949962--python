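"""Synthetic leaf-lesion dataset generator and on-disk dataset handling.

The real study corpus (26 disease classes, 200 images each, plain-background
leaf photographs with annotated lesion masks) is not publicly released, so
the pipeline is exercised on a generated stand-in: superellipse leaf
silhouettes with sinusoidally perturbed edges on a flat noisy background,
lesions drawn as unions of Gaussian blobs in three spatial patterns
(``fragmented`` — many small blobs, ``concentrated`` — one large blob,
``mixed`` — both), and the infected-area fraction (POI) driven into a
requested severity band by a monotone binary search on the blob scale.
Each class carries a fixed lesion hue and speckle frequency from a seeded
table, so classes are statistically separable and the classification head
has learnable signal.

On disk a dataset is ``{images/, masks/, leaf_masks/, manifest.csv}`` with
8-bit PNGs (masks: 0 background / 255 foreground) and a manifest with
columns (image_path, mask_path, leaf_mask_path, label, split, poi, severity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .losses import SEVERITY_BANDS, severity_band

PATTERNS = ("fragmented", "concentrated", "mixed")
_BAND_RANGES = {"light": (0.0, 0.2), "moderate": (0.2, 0.5), "severe": (0.5, 1.0)}
_EDGE_MARGIN = 0.005  # keep generated POI this far inside open band edges


class GenerationError(RuntimeError):
    """Raised when a requested severity band cannot be realised."""


@dataclass
class SyntheticSpec:
    n_classes: int = 26
    images_per_class: int = 200
    image_size: int = 256
    severity_mix: tuple = (1 / 3, 1 / 3, 1 / 3)     # light, moderate, severe
    pattern_mix: tuple = (1 / 3, 1 / 3, 1 / 3)      # fragmented, concentrated, mixed
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.images_per_class < 1:
            raise ValueError("counts must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        for mix, name in ((self.severity_mix, "severity_mix"),
                          (self.pattern_mix, "pattern_mix")):
            if len(mix) != 3 or abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError(f"{name} must be 3 nonnegative proportions summing to 1")


@dataclass
class ImageSample:
    image: np.ndarray        # (3, H, W) float in [0, 1]
    lesion_mask: np.ndarray  # (H, W) uint8 in {0, 1}
    leaf_mask: np.ndarray    # (H, W) uint8 in {0, 1}
    label: int
    split: str = "train"
    poi: float = 0.0
    pattern: str = "mixed"


def class_style(class_id: int, n_classes: int) -> dict:
    """Fixed per-class lesion appearance from a seeded table."""
    rng = np.random.default_rng(916_001 + class_id)
    hue = (0.02 + class_id / n_classes + rng.uniform(-0.004, 0.004)) % 1.0
    return {
        "hue": hue,
        "sat": 0.72 + rng.uniform(-0.05, 0.05),
        "val": 0.52 + rng.uniform(-0.05, 0.05),
        "speckle_freq": 3 + int(rng.integers(0, 5)),
        "speckle_amp": 0.10 + rng.uniform(0.0, 0.08),
    }


def _leaf_silhouette(size: int, rng: np.random.Generator) -> np.ndarray:
    """Randomised superellipse with sinusoidal edge perturbation."""
    yy, xx = np.mgrid[0:size, 0:size]
    cx = size * (0.5 + rng.uniform(-0.03, 0.03))
    cy = size * (0.5 + rng.uniform(-0.03, 0.03))
    a = size * rng.uniform(0.32, 0.42)
    b = size * rng.uniform(0.28, 0.40)
    n = rng.uniform(1.8, 3.2)
    rot = rng.uniform(0, np.pi)
    amp = rng.uniform(0.02, 0.06)
    k = int(rng.integers(4, 9))
    phase = rng.uniform(0, 2 * np.pi)
    x = (xx - cx) * np.cos(rot) + (yy - cy) * np.sin(rot)
    y = -(xx - cx) * np.sin(rot) + (yy - cy) * np.cos(rot)
    theta = np.arctan2(y, x)
    r = np.hypot(x, y)
    with np.errstate(divide="ignore"):
        radius = (np.abs(np.cos(theta) / a) ** n +
                  np.abs(np.sin(theta) / b) ** n) ** (-1.0 / n)
    radius = radius * (1.0 + amp * np.sin(k * theta + phase))
    return (r <= radius).astype(np.uint8)


def _blob_params(pattern: str, size: int, rng: np.random.Generator):
    """Relative blob widths per spatial pattern."""
    if pattern == "fragmented":
        n = int(rng.integers(8, 16))
        sig = rng.uniform(0.020, 0.045, n)
    elif pattern == "concentrated":
        n = 1
        sig = rng.uniform(0.16, 0.24, 1)
    elif pattern == "mixed":
        n_small = int(rng.integers(4, 9))
        sig = np.concatenate([rng.uniform(0.10, 0.16, 1),
                              rng.uniform(0.020, 0.045, n_small)])
        n = sig.size
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return sig * size


def _lesion_mask(leaf: np.ndarray, pattern: str, band: str, size: int,
                 rng: np.random.Generator) -> np.ndarray:
    lo, hi = _BAND_RANGES[band]
    leaf_idx = np.flatnonzero(leaf)
    if leaf_idx.size < 16:
        raise GenerationError(
            f"leaf too small ({leaf_idx.size} px) to host lesions in band {band!r}")
    sigmas = _blob_params(pattern, size, rng)
    centers = leaf_idx[rng.integers(0, leaf_idx.size, sigmas.size)]
    cy, cx = np.divmod(centers, size)
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy[None] - cy[:, None, None]) ** 2 + (xx[None] - cx[:, None, None]) ** 2

    def poi_at(scale: float) -> tuple[float, np.ndarray]:
        fld = np.exp(-d2 / (2.0 * (scale * sigmas[:, None, None]) ** 2)).max(axis=0)
        lesion = ((fld >= 0.5) & (leaf > 0)).astype(np.uint8)
        return lesion.sum() / leaf_idx.size, lesion

    target = lo + (hi - lo) * rng.uniform(0.3, 0.7)
    t_lo, t_hi = 0.02, 60.0
    best = None
    for _ in range(48):
        t = np.sqrt(t_lo * t_hi)
        poi, lesion = poi_at(t)
        if lo + _EDGE_MARGIN < poi <= hi - (_EDGE_MARGIN if hi < 1.0 else 0.0):
            best = lesion
            if abs(poi - target) < 0.02:
                break
        if poi < target:
            t_lo = t
        else:
            t_hi = t
    if best is None:
        raise GenerationError(
            f"could not reach severity band {band!r} ({lo}, {hi}] for pattern "
            f"{pattern!r} on a leaf of {leaf_idx.size} px")
    return best


def _render(leaf: np.ndarray, lesion: np.ndarray, style: dict, size: int,
            rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    h = np.full((size, size), 0.09) + rng.normal(0, 0.01, (size, size))
    s = np.full((size, size), 0.12) + rng.normal(0, 0.02, (size, size))
    v = np.full((size, size), 0.82) + rng.normal(0, 0.02, (size, size))
    # leaf body: green with a mild illumination gradient
    grad = 0.08 * (xx / size - 0.5) * rng.uniform(-1, 1)
    h[leaf > 0] = 0.30 + rng.normal(0, 0.01)
    s[leaf > 0] = 0.58 + rng.normal(0, 0.03) + rng.normal(0, 0.015, int(leaf.sum()))
    v[leaf > 0] = 0.46 + grad[leaf > 0] + rng.normal(0, 0.02, int(leaf.sum()))
    # lesions: class hue + speckle texture
    f = style["speckle_freq"]
    speckle = style["speckle_amp"] * (np.sin(2 * np.pi * f * xx / size) *
                                      np.sin(2 * np.pi * f * yy / size))
    m = lesion > 0
    h[m] = (style["hue"] + rng.normal(0, 0.008) +
            rng.normal(0, 0.004, int(m.sum()))) % 1.0
    s[m] = style["sat"] + rng.normal(0, 0.02, int(m.sum()))
    v[m] = style["val"] + speckle[m] + rng.normal(0, 0.02, int(m.sum()))
    hsv = np.stack([np.clip(h, 0, 1), np.clip(s, 0, 1), np.clip(v, 0, 1)], axis=-1)
    rgb = hsv_to_rgb(hsv) + rng.normal(0, 0.008, (size, size, 3))
    return np.clip(rgb, 0.0, 1.0).transpose(2, 0, 1)


def generate_sample(spec: SyntheticSpec, class_id: int, severity: str,
                    pattern: str, seed: int) -> ImageSample:
    """Generate one labelled sample with its POI strictly inside ``severity``.

    Identical arguments yield bit-identical samples.
    """
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} outside [0, {spec.n_classes})")
    if severity not in SEVERITY_BANDS:
        raise ValueError(f"unknown severity band {severity!r}")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), class_id,
                                 SEVERITY_BANDS.index(severity),
                                 PATTERNS.index(pattern)])
    rng = np.random.default_rng(ss)
    size = spec.image_size
    leaf = _leaf_silhouette(size, rng)
    lesion = _lesion_mask(leaf, pattern, severity, size, rng)
    style = class_style(class_id, spec.n_classes)
    image = _render(leaf, lesion, style, size, rng)
    poi = float(lesion.sum() / leaf.sum())
    assert severity_band(poi) == severity
    return ImageSample(image=image, lesion_mask=lesion, leaf_mask=leaf,
                       label=class_id, poi=poi, pattern=pattern)


# ---------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------

def _largest_remainder(mix, n: int) -> list[int]:
    raw = np.asarray(mix, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def write_mask_png(path: Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, "L").save(path)


def read_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_image_png(path: Path, image: np.ndarray) -> None:
    arr = (np.clip(image, 0, 1).transpose(1, 2, 0) * 255).round().astype(np.uint8)
    Image.fromarray(arr, "RGB").save(path)


def read_image_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
    return arr.transpose(2, 0, 1)


def generate_dataset(spec: SyntheticSpec, out_dir) -> pd.DataFrame:
    """Write a dataset to ``out_dir`` and return its manifest.

    Per class: severities and patterns follow the spec's mixes (largest
    remainder), and the train/test split is 8:2, stratified by class with
    evenly spaced test indices.  Fully deterministic given ``spec.seed``.
    """
    out = Path(out_dir)
    for sub in ("images", "masks", "leaf_masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    n = spec.images_per_class
    sev_counts = _largest_remainder(spec.severity_mix, n)
    sev_list = [b for b, c in zip(SEVERITY_BANDS, sev_counts) for _ in range(c)]
    pat_counts = _largest_remainder(spec.pattern_mix, n)
    pat_list = [p for p, c in zip(PATTERNS, pat_counts) for _ in range(c)]
    n_test = n - int(round(0.8 * n))
    test_ids = set(np.linspace(0, n - 1, n_test).round().astype(int)) if n_test else set()
    rows = []
    for c in range(spec.n_classes):
        shuffle_rng = np.random.default_rng([spec.seed % (2 ** 31), c, 77])
        sev_assign = list(shuffle_rng.permutation(sev_list))
        pat_assign = list(shuffle_rng.permutation(pat_list))
        for i in range(n):
            severity = sev_assign[i]
            pattern = pat_assign[i]
            seed_ci = (spec.seed * 1_000_003 + c * 10_007 + i) % (2 ** 31)
            sample = generate_sample(spec, c, severity, pattern, seed_ci)
            stem = f"c{c:03d}_{i:04d}.png"
            write_image_png(out / "images" / stem, sample.image)
            write_mask_png(out / "masks" / stem, sample.lesion_mask)
            write_mask_png(out / "leaf_masks" / stem, sample.leaf_mask)
            rows.append({
                "image_path": f"images/{stem}",
                "mask_path": f"masks/{stem}",
                "leaf_mask_path": f"leaf_masks/{stem}",
                "label": c,
                "split": "test" if i in test_ids else "train",
                "poi": sample.poi,
                "severity": severity,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(path) -> tuple[pd.DataFrame, Path]:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return pd.read_csv(path), path.parent


def stratify_by_severity(manifest: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a manifest into light/moderate/severe sub-manifests by POI."""
    if "poi" not in manifest.columns:
        raise ValueError("manifest lacks a 'poi' column")
    poi = manifest["poi"].to_numpy(dtype=float)
    if len(poi) and ((poi <= 0) | (poi > 1)).any():
        bad = poi[(poi <= 0) | (poi > 1)][0]
        raise ValueError(f"POI outside (0, 1]: {bad}")
    out = {}
    for band in SEVERITY_BANDS:
        lo, hi = _BAND_RANGES[band]
        out[band] = manifest[(poi > lo) & (poi <= hi)]
    return out
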