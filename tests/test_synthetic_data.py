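"""Synthetic leaf-lesion generator: determinism, POI control, dataset layout."""

import numpy as np
import pandas as pd
import pytest

import leafsam as ls
from leafsam.data import (PATTERNS, class_style, read_mask_png, read_image_png)
from leafsam.losses import SEVERITY_BANDS


SPEC = ls.SyntheticSpec(n_classes=4, images_per_class=10, image_size=64, seed=7)


def test_spec_validation():
    with pytest.raises(ValueError):
        ls.SyntheticSpec(n_classes=0)
    with pytest.raises(ValueError):
        ls.SyntheticSpec(image_size=16)
    with pytest.raises(ValueError):
        ls.SyntheticSpec(severity_mix=(0.5, 0.5, 0.5))


def test_generate_sample_deterministic():
    a = ls.generate_sample(SPEC, 1, "moderate", "mixed", seed=11)
    b = ls.generate_sample(SPEC, 1, "moderate", "mixed", seed=11)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.lesion_mask, b.lesion_mask)
    assert np.array_equal(a.leaf_mask, b.leaf_mask)
    c = ls.generate_sample(SPEC, 1, "moderate", "mixed", seed=12)
    assert not np.array_equal(a.lesion_mask, c.lesion_mask)


@pytest.mark.parametrize("band,lo,hi", [
    ("light", 0.0, 0.2), ("moderate", 0.2, 0.5), ("severe", 0.5, 1.0)])
@pytest.mark.parametrize("pattern", PATTERNS)
def test_generated_poi_inside_band(band, lo, hi, pattern):
    s = ls.generate_sample(SPEC, 0, band, pattern, seed=5)
    assert lo < s.poi <= hi
    assert ls.severity_band(s.poi) == band


def test_lesion_subset_of_leaf_and_binary():
    for seed in range(4):
        s = ls.generate_sample(SPEC, 2, "moderate", "fragmented", seed=seed)
        assert set(np.unique(s.lesion_mask)) <= {0, 1}
        assert set(np.unique(s.leaf_mask)) <= {0, 1}
        assert int((s.lesion_mask & ~s.leaf_mask.astype(bool)).sum()) == 0
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0


def test_generate_sample_validates_arguments():
    with pytest.raises(ValueError):
        ls.generate_sample(SPEC, 9, "light", "mixed", seed=0)
    with pytest.raises(ValueError):
        ls.generate_sample(SPEC, 0, "extreme", "mixed", seed=0)
    with pytest.raises(ValueError):
        ls.generate_sample(SPEC, 0, "light", "spiral", seed=0)


def test_dataset_layout_split_and_poi_consistency(tmp_path):
    manifest = ls.generate_dataset(SPEC, tmp_path)
    assert len(manifest) == 40
    assert (manifest["split"] == "train").sum() == 32
    assert (manifest["split"] == "test").sum() == 8
    # split stratified by class: 8 train / 2 test each
    per_class = manifest.groupby("label")["split"].value_counts()
    for c in range(4):
        assert per_class[c]["train"] == 8 and per_class[c]["test"] == 2
    # manifest POI equals recomputation from the written PNGs
    for _, row in manifest.iterrows():
        lesion = read_mask_png(tmp_path / row["mask_path"])
        leaf = read_mask_png(tmp_path / row["leaf_mask_path"])
        poi = lesion.sum() / leaf.sum()
        assert abs(poi - row["poi"]) < 1e-9
        assert ls.severity_band(poi) == row["severity"]
    img = read_image_png(tmp_path / manifest.iloc[0]["image_path"])
    assert img.shape == (3, 64, 64)


def test_dataset_byte_identical_across_runs(tmp_path):
    ls.generate_dataset(SPEC, tmp_path / "a")
    ls.generate_dataset(SPEC, tmp_path / "b")
    ma = (tmp_path / "a" / "manifest.csv").read_bytes()
    mb = (tmp_path / "b" / "manifest.csv").read_bytes()
    assert ma == mb
    name = pd.read_csv(tmp_path / "a" / "manifest.csv").iloc[3]["image_path"]
    assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_stratify_by_severity_boundaries():
    df = pd.DataFrame({"poi": [0.1, 0.2, 0.21, 0.5, 0.51],
                       "image_path": list("abcde")})
    parts = ls.stratify_by_severity(df)
    assert sorted(parts["light"]["poi"]) == [0.1, 0.2]
    assert sorted(parts["moderate"]["poi"]) == [0.21, 0.5]
    assert sorted(parts["severe"]["poi"]) == [0.51]
    assert sum(len(p) for p in parts.values()) == len(df)


def test_stratify_empty_and_invalid():
    empty = pd.DataFrame({"poi": []})
    parts = ls.stratify_by_severity(empty)
    assert all(len(p) == 0 for p in parts.values())
    with pytest.raises(ValueError):
        ls.stratify_by_severity(pd.DataFrame({"poi": [0.0]}))
    with pytest.raises(ValueError):
        ls.stratify_by_severity(pd.DataFrame({"x": [1]}))


def test_class_hues_separable():
    """Mean lesion hue differs between classes by more than generator noise."""
    import matplotlib.colors as mcolors
    spec = ls.SyntheticSpec(n_classes=3, images_per_class=50, image_size=48, seed=1)
    means = []
    for c in range(spec.n_classes):
        hues = []
        for i in range(50):
            s = ls.generate_sample(spec, c, "moderate", "concentrated", seed=100 + i)
            rgb = s.image.transpose(1, 2, 0)[s.lesion_mask > 0]
            hues.append(mcolors.rgb_to_hsv(rgb)[:, 0].mean())
        means.append(np.mean(hues))
    noise_scale = 0.012  # per-sample hue jitter in the generator
    for a in range(3):
        for b in range(a + 1, 3):
            d = abs(means[a] - means[b])
            d = min(d, 1 - d)  # circular hue distance
            assert d > noise_scale, (a, b, d)


def test_class_style_fixed_table():
    s1 = class_style(3, 26)
    s2 = class_style(3, 26)
    assert s1 == s2
    assert class_style(4, 26)["hue"] != s1["hue"]
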