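"""Closed-form loss identities, metric–oracle equivalence, severity grading."""

import itertools
import math

import numpy as np
import pytest

import leafsam as ls
from leafsam import tensor as T


# -- losses ------------------------------------------------------------

def test_dice_loss_closed_forms():
    y = np.array([[1.0, 0.0], [1.0, 0.0]])
    assert abs(ls.dice_loss(y, y).item()) < 1e-6          # perfect overlap
    zero = np.zeros_like(y)
    assert abs(ls.dice_loss(zero, y).item() - 1.0) < 1e-5  # no overlap
    p = np.array([[1.0, 1.0], [0.0, 0.0]])
    g = np.array([[1.0, 0.0], [1.0, 0.0]])
    assert abs(ls.dice_loss(p, g).item() - 0.5) < 1e-6     # 1 - 2/(2+2)


def test_dice_loss_rejects_soft_target():
    with pytest.raises(ValueError):
        ls.dice_loss(np.zeros((2, 2)), np.full((2, 2), 0.5))


def test_bce_loss_closed_forms():
    y = np.array([[1.0, 0.0], [0.0, 1.0]])
    half = np.full((2, 2), 0.5)
    assert abs(ls.bce_loss(half, y).item() - math.log(2)) < 1e-9
    assert ls.bce_loss(y, y).item() < 1e-6                 # exact under clipping
    single = ls.bce_loss(np.array([[0.9]]), np.array([[1.0]]))
    assert abs(single.item() + math.log(0.9)) < 1e-9


def test_iou_loss_closed_forms():
    p = np.array([[1.0, 1.0], [0.0, 0.0]])
    g = np.array([[1.0, 0.0], [1.0, 0.0]])
    assert abs(ls.iou_loss(p, g).item() - (1 - 1 / 3)) < 1e-6
    assert ls.iou_loss(g, g).item() < 1e-6
    z = np.zeros((2, 2))
    assert abs(ls.iou_loss(z, z).item()) < 1e-6            # empty-empty -> 0


def test_cls_loss_closed_forms():
    uniform = np.zeros(26)
    assert abs(ls.cls_loss(uniform, 3).item() - math.log(26)) < 1e-9
    favored = np.zeros(26)
    favored[5] = 20.0
    assert ls.cls_loss(favored, 5).item() < 1e-6
    shifted = ls.cls_loss(uniform + 7.3, 3)
    assert abs(shifted.item() - math.log(26)) < 1e-9       # shift invariance
    with pytest.raises(ValueError):
        ls.cls_loss(uniform, 26)


def test_joint_loss_linearity_and_weights(rng):
    probs = rng.random((4, 4))
    mask = (rng.random((4, 4)) > 0.5).astype(float)
    logits = rng.standard_normal(5)
    w = ls.LossWeights()
    total, comps = ls.joint_loss(probs, None, logits, mask, 2, w)
    expect = 0.6 * comps["mask"] + 0.2 * comps["iou"] + 0.2 * comps["cls"]
    assert abs(total.item() - expect) < 1e-12
    # published best weight triple on fixed component losses
    assert abs(0.6 * 0.5 + 0.2 * 0.3 + 0.2 * 1.0 - 0.56) < 1e-12
    w0 = ls.LossWeights(lambda_mask=0, lambda_iou=0, lambda_cls=0)
    assert ls.joint_loss(probs, None, logits, mask, 2, w0)[0].item() == 0.0
    w2 = ls.LossWeights(lambda_mask=1.2, lambda_iou=0.4, lambda_cls=0.4)
    doubled, _ = ls.joint_loss(probs, None, logits, mask, 2, w2)
    assert abs(doubled.item() - 2 * total.item()) < 1e-12


def test_joint_loss_gradients_reach_both_heads(rng):
    mask_logits = T.Tensor(rng.standard_normal((1, 4, 4)), requires_grad=True)
    class_logits = T.Tensor(rng.standard_normal((1, 5)), requires_grad=True)
    target = (rng.random((1, 4, 4)) > 0.5).astype(float)
    total, _ = ls.joint_loss(T.sigmoid(mask_logits), None, class_logits,
                             target, np.array([1]), ls.LossWeights())
    total.backward()
    assert np.abs(mask_logits.grad).max() > 0
    assert np.abs(class_logits.grad).max() > 0


# -- metrics -----------------------------------------------------------

def test_seg_metrics_exhaustive_2x2_oracle():
    """Dice/IoU equal exhaustive pixel counting on all 256 2x2 mask pairs."""
    for bits in itertools.product([0, 1], repeat=8):
        p = np.array(bits[:4]).reshape(2, 2)
        g = np.array(bits[4:]).reshape(2, 2)
        dice, iou = ls.seg_metrics(p, g)
        inter = int((p & g).sum())
        union = int((p | g).sum())
        if p.sum() + g.sum() == 0:
            assert dice == iou == 1.0
        else:
            assert dice == pytest.approx(2 * inter / (p.sum() + g.sum()), abs=1e-15)
            assert iou == pytest.approx(inter / union, abs=1e-15)


def test_dice_iou_identity_random_masks(rng):
    """Dice = 2*IoU/(1+IoU) on random 32x32 mask pairs."""
    for _ in range(200):
        p = (rng.random((32, 32)) > 0.5).astype(int)
        g = (rng.random((32, 32)) > 0.5).astype(int)
        dice, iou = ls.seg_metrics(p, g)
        assert abs(dice - 2 * iou / (1 + iou)) < 1e-12


def test_seg_metrics_rejects_nonbinary():
    with pytest.raises(ValueError):
        ls.seg_metrics(np.full((2, 2), 0.5), np.zeros((2, 2)))


def test_classification_accuracy():
    assert ls.losses.classification_accuracy(3, 5, 1, 1) == pytest.approx(0.8)
    assert ls.losses.classification_accuracy(4, 0, 0, 0) == 1.0
    with pytest.raises(ValueError):
        ls.losses.classification_accuracy(0, 0, 0, 0)
    labels = np.array([0, 1, 2, 1])
    assert ls.losses.accuracy_from_labels(labels, labels) == 1.0
    assert ls.losses.accuracy_from_labels([0, 1, 1, 1], labels) == pytest.approx(0.75)


# -- severity ----------------------------------------------------------

def _disc_masks(pi: int, pt: int):
    leaf = np.zeros(100, dtype=int)
    leaf[:pt] = 1
    lesion = np.zeros(100, dtype=int)
    lesion[:pi] = 1
    return lesion.reshape(10, 10), leaf.reshape(10, 10)


@pytest.mark.parametrize("pi,pt,band", [
    (30, 100, "moderate"),
    (100, 100, "severe"),
    (20, 100, "light"),     # boundary belongs to the lower band
    (21, 100, "moderate"),
    (50, 100, "moderate"),
    (51, 100, "severe"),
])
def test_poi_severity_bands(pi, pt, band):
    rec = ls.poi_severity(*_disc_masks(pi, pt))
    assert rec.poi == pytest.approx(pi / pt, abs=1e-12)
    assert rec.band == band


def test_poi_severity_errors():
    lesion, leaf = _disc_masks(10, 50)
    with pytest.raises(ValueError):
        ls.poi_severity(lesion, np.zeros_like(leaf))       # empty leaf
    outside = np.zeros_like(leaf)
    outside[-1, -1] = 1
    with pytest.raises(ValueError):
        ls.poi_severity(outside, leaf)                     # lesion outside leaf
    with pytest.raises(ValueError):
        ls.severity_band(0.0)
    with pytest.raises(ValueError):
        ls.severity_band(1.2)
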