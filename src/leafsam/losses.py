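"""Joint training objective, evaluation metrics and severity grading.

The objective combines a mask loss (Dice + binary cross-entropy), a soft-IoU
loss, and a classification cross-entropy:

    L_mask  = a * L_Dice + b * L_BCE
    L_joint = lambda_mask * L_mask + lambda_iou * L_IoU + lambda_cls * L_cls

with default weights (0.6, 0.2, 0.2) — the best row of the weight ablation —
and a = b = 0.5 inside the mask loss.  Evaluation uses hard Dice/IoU and
accuracy; severity grading uses the percentage-of-infection (POI): lesion
pixels over leaf pixels, banded light (0, 0.2], moderate (0.2, 0.5],
severe (0.5, 1], with boundaries belonging to the lower band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tensor as T
from .config import LossWeights
from .tensor import Tensor

EPS = 1e-6
SEVERITY_BANDS = ("light", "moderate", "severe")


def _as_prob_tensor(pred) -> Tensor:
    return pred if isinstance(pred, Tensor) else T.as_tensor(np.asarray(pred, dtype=np.float64))


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")
    return arr.astype(np.float64)


# ---------------------------------------------------------------------
# losses (differentiable; accept Tensor or array predictions)
# ---------------------------------------------------------------------

def dice_loss(pred_probs, target) -> Tensor:
    """Soft Dice loss ``1 - 2*sum(py)/(sum(p^2)+sum(y^2))`` with eps smoothing."""
    p = _as_prob_tensor(pred_probs)
    y = _check_binary(target, "target")
    num = T.tsum(p * y) * 2.0 + EPS
    den = T.tsum(p * p) + float((y * y).sum()) + EPS
    return 1.0 - num / den


def bce_loss(pred_probs, target) -> Tensor:
    """Pixel-mean binary cross-entropy; probabilities clipped to [1e-7, 1-1e-7]."""
    p = T.clip(_as_prob_tensor(pred_probs), 1e-7, 1.0 - 1e-7)
    y = _check_binary(target, "target")
    ll = T.tlog(p) * y + T.tlog(1.0 - p) * (1.0 - y)
    return -T.tmean(ll)


def iou_loss(pred_probs, target) -> Tensor:
    """Soft IoU loss ``1 - |P∩G| / |P∪G|`` on probability masks."""
    p = _as_prob_tensor(pred_probs)
    y = _check_binary(target, "target")
    inter = T.tsum(p * y)
    union = T.tsum(p) + float(y.sum()) - inter
    return 1.0 - (inter + EPS) / (union + EPS)


def cls_loss(class_logits, label) -> Tensor:
    """Cross-entropy ``-log softmax(logits)[label]``, batch-mean."""
    logits = _as_prob_tensor(class_logits)
    if logits.ndim == 1:
        logits = T.reshape(logits, (1, -1))
        label = np.atleast_1d(label)
    label = np.asarray(label, dtype=int)
    c = logits.shape[-1]
    if (label < 0).any() or (label >= c).any():
        raise ValueError(f"label out of range [0, {c})")
    ls = T.log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(label.size), label] = 1.0
    return -T.tmean(T.tsum(ls * onehot, axis=-1))


def _per_image_mean(loss_fn, pred, target) -> Tensor:
    """Region losses are defined per image; average them over a batch."""
    p = _as_prob_tensor(pred)
    target = np.asarray(target)
    if p.ndim == 2:
        return loss_fn(p, target)
    terms = [loss_fn(p[i], target[i]) for i in range(p.shape[0])]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def joint_loss(mask_probs, iou_probs_unused, class_logits, target_mask, label,
               w: LossWeights | None = None):
    """Linear combination of the three objectives; returns (total, components).

    ``components`` is a dict of python floats for logging; ``total`` is a
    Tensor participating in the graph.
    """
    w = w or LossWeights()
    l_dice = _per_image_mean(dice_loss, mask_probs, target_mask)
    l_bce = bce_loss(mask_probs, target_mask)
    l_mask = l_dice * w.alpha_dice + l_bce * w.beta_bce
    l_iou = _per_image_mean(iou_loss, mask_probs, target_mask)
    l_cls = cls_loss(class_logits, label)
    total = l_mask * w.lambda_mask + l_iou * w.lambda_iou + l_cls * w.lambda_cls
    comps = {"dice": l_dice.item(), "bce": l_bce.item(), "mask": l_mask.item(),
             "iou": l_iou.item(), "cls": l_cls.item(), "total": total.item()}
    return total, comps


# ---------------------------------------------------------------------
# metrics (pure numpy, hard masks)
# ---------------------------------------------------------------------

def seg_metrics(pred_mask, target_mask) -> tuple[float, float]:
    """Hard Dice and IoU; both 1.0 when prediction and target are empty."""
    p = _check_binary(pred_mask, "pred_mask")
    g = _check_binary(target_mask, "target_mask")
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    inter = float((p * g).sum())
    ps, gs = float(p.sum()), float(g.sum())
    union = ps + gs - inter
    if ps + gs == 0:
        return 1.0, 1.0
    return 2.0 * inter / (ps + gs), inter / union


def classification_accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP+TN) / (TP+TN+FP+FN) from aggregated confusion counts."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("no instances")
    return (tp + tn) / total


def accuracy_from_labels(pred_labels, true_labels) -> float:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0:
        raise ValueError("no instances")
    correct = int((pred == true).sum())
    return classification_accuracy(correct, 0, pred.size - correct, 0)


# ---------------------------------------------------------------------
# severity grading
# ---------------------------------------------------------------------

@dataclass
class SeverityRecord:
    poi: float
    band: str


def severity_band(poi: float) -> str:
    """Band of a POI fraction; right band edges closed (0.2 -> light)."""
    if not 0.0 < poi <= 1.0:
        raise ValueError(f"POI must lie in (0, 1], got {poi}")
    if poi <= 0.2:
        return "light"
    if poi <= 0.5:
        return "moderate"
    return "severe"


def poi_severity(lesion_mask, leaf_mask) -> SeverityRecord:
    """POI = lesion pixels / leaf pixels, with its light/moderate/severe band."""
    lesion = _check_binary(lesion_mask, "lesion_mask")
    leaf = _check_binary(leaf_mask, "leaf_mask")
    if leaf.sum() == 0:
        raise ValueError("leaf mask is empty")
    if (lesion * (1.0 - leaf)).sum() > 0:
        raise ValueError("lesion pixels outside the leaf mask")
    poi = float(lesion.sum() / leaf.sum())
    return SeverityRecord(poi=poi, band=severity_band(poi))


# ---------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------

@dataclass
class EvalReport:
    mean_dice: float
    mean_iou: float
    accuracy: float
    per_severity: dict = field(default_factory=dict)   # band -> {dice, iou, n}
    per_class_accuracy: dict = field(default_factory=dict)
    n_images: int = 0
    failures: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def severity_table(self) -> pd.DataFrame:
        rows = [{"severity": b, **self.per_severity.get(b, {})}
                for b in SEVERITY_BANDS]
        return pd.DataFrame(rows)
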