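"""Training, evaluation and prediction pipeline.

Training follows the published schedule: AdamW over the trainable groups
only (adapters, local branch, fusion modules, decoder heads — the ViT
backbone stays frozen), an exponentially decaying learning rate
``lr(t) = lr0 * exp(-k t)`` (default ``k = ln(10)/total_steps``, one decade
over the run), batch size 4, and the epoch-scheduled SE coefficient passed
into every forward pass.  Evaluation reports mean Dice/IoU, classification
accuracy, and Dice/IoU stratified by severity band of the ground-truth POI.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import tensor as T
from .config import TrainConfig
from .data import (load_manifest, read_image_png, read_mask_png,
                   stratify_by_severity, write_mask_png)
from .losses import (EvalReport, SEVERITY_BANDS, accuracy_from_labels,
                     joint_loss, seg_metrics)
from .model import LeafSam
from .optim import AdamW

log = logging.getLogger("leafsam")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def lr_schedule(t: int, lr0: float, k: float) -> float:
    """Exponentially decaying learning rate ``lr0 * exp(-k t)``."""
    if t < 0:
        raise ValueError("step index must be >= 0")
    return lr0 * math.exp(-k * t)


def default_decay_k(total_steps: int) -> float:
    """One decade of decay over the whole run."""
    return math.log(10.0) / max(1, total_steps)


@dataclass
class TrainResult:
    checkpoint_path: Path | None
    history: list = field(default_factory=list)   # per-step loss components
    final_train_dice: float = 0.0
    final_train_accuracy: float = 0.0
    model: LeafSam | None = None


def _load_arrays(manifest, root: Path):
    images, masks, labels = [], [], []
    for _, row in manifest.iterrows():
        images.append(read_image_png(root / row["image_path"]))
        masks.append(read_mask_png(root / row["mask_path"]).astype(np.float64))
        labels.append(int(row["label"]))
    return np.stack(images), np.stack(masks), np.asarray(labels)


def _optimizer_for(model: LeafSam, cfg: TrainConfig) -> AdamW:
    decay, no_decay = [], []
    for p in model.trainable_parameters():
        (decay if p.data.ndim >= 2 else no_decay).append(p)
    return AdamW([{"params": decay, "weight_decay": cfg.weight_decay},
                  {"params": no_decay, "weight_decay": 0.0}], lr=cfg.lr0)


def train(cfg: TrainConfig, manifest_path, max_steps: int | None = None,
          model: LeafSam | None = None, save_checkpoint: bool = True) -> TrainResult:
    """Run the training loop on the train split of a dataset manifest."""
    manifest, root = load_manifest(manifest_path)
    train_df = manifest[manifest["split"] == "train"]
    if not len(train_df):
        raise ValueError("manifest has no train rows")
    images, masks, labels = _load_arrays(train_df, root)
    n = len(train_df)
    if model is None:
        model = LeafSam.from_preset(
            cfg.preset, seed=cfg.seed,
            num_classes=cfg.num_classes, ffm_beta=cfg.ffm_beta,
            **cfg.model_overrides)
    frozen_before = {name: p.data.copy()
                     for name, p in model.named_parameters()
                     if not p.requires_grad}
    opt = _optimizer_for(model, cfg)
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    total_steps = max_steps if max_steps is not None \
        else cfg.epochs * steps_per_epoch
    k = cfg.lr_decay_k if cfg.lr_decay_k is not None else default_decay_k(total_steps)
    order_rng = np.random.default_rng(cfg.seed)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_fh = open(out_dir / "metrics.jsonl", "w")

    history = []
    model.train()
    step = 0
    epoch = 0
    while step < total_steps:
        perm = order_rng.permutation(n)
        for b0 in range(0, n, cfg.batch_size):
            if step >= total_steps:
                break
            idx = perm[b0:b0 + cfg.batch_size]
            opt.lr = lr_schedule(step, cfg.lr0, k)
            opt.zero_grad()
            out = model(images[idx], epoch=epoch)
            probs = T.sigmoid(out.mask_logits)
            total, comps = joint_loss(probs, out.iou_estimate, out.class_logits,
                                      masks[idx], labels[idx], cfg.loss)
            total.backward()
            opt.step()
            rec = {"step": step, "epoch": epoch, "lr": opt.lr, **comps}
            history.append(rec)
            metrics_fh.write(json.dumps(rec) + "\n")
            if step % 25 == 0:
                log.info("step %d epoch %d loss %.4f (dice %.3f bce %.3f "
                         "iou %.3f cls %.3f)", step, epoch, comps["total"],
                         comps["dice"], comps["bce"], comps["iou"], comps["cls"])
            step += 1
        epoch += 1
    metrics_fh.close()

    # frozen parameters must be bit-identical to their initial values
    for name, p in model.named_parameters():
        if not p.requires_grad and not np.array_equal(p.data, frozen_before[name]):
            raise RuntimeError(f"frozen parameter {name} changed during training")

    # training-set metrics with the final weights
    model.eval()
    dices, preds = [], []
    with T.no_grad():
        for b0 in range(0, n, cfg.batch_size):
            sl = slice(b0, b0 + cfg.batch_size)
            out = model(images[sl], epoch=epoch)
            pm = (1.0 / (1.0 + np.exp(-out.mask_logits.data)) > 0.5).astype(np.uint8)
            for j in range(pm.shape[0]):
                dices.append(seg_metrics(pm[j], masks[sl][j])[0])
            preds.extend(out.class_logits.data.argmax(axis=1).tolist())
    result = TrainResult(checkpoint_path=None, history=history,
                         final_train_dice=float(np.mean(dices)),
                         final_train_accuracy=accuracy_from_labels(preds, labels),
                         model=model)
    if save_checkpoint:
        ckpt = out_dir / "checkpoint.npz"
        model.save(ckpt, extra={"seed": cfg.seed, "train": cfg.to_dict(),
                                "steps": total_steps})
        result.checkpoint_path = ckpt
    log.info("training done: %d steps, train Dice %.4f, train accuracy %.4f",
             total_steps, result.final_train_dice, result.final_train_accuracy)
    return result


# ---------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------

def evaluate_masks(manifest, root: Path, predictions: dict) -> EvalReport:
    """Score per-image predictions against a manifest.

    ``predictions`` maps image_path -> (pred_mask uint8 HxW, pred_label int).
    Per-image Dice/IoU are averaged within each severity stratum of the
    ground-truth POI and overall.
    """
    strata = stratify_by_severity(manifest)
    dices, ious, preds, trues = [], [], [], []
    per_sev = {}
    per_class: dict[int, list] = {}
    failures = []
    scored = {}
    for _, row in manifest.iterrows():
        key = row["image_path"]
        try:
            gt = read_mask_png(root / row["mask_path"])
            pred_mask, pred_label = predictions[key]
            d, i = seg_metrics(pred_mask, gt)
        except Exception as exc:  # noqa: BLE001 - collected per item
            failures.append(f"{key}: {exc}")
            continue
        scored[key] = (d, i)
        dices.append(d)
        ious.append(i)
        preds.append(pred_label)
        trues.append(int(row["label"]))
        per_class.setdefault(int(row["label"]), []).append(
            int(pred_label == row["label"]))
    for band in SEVERITY_BANDS:
        sub = strata[band]
        vals = [scored[r["image_path"]] for _, r in sub.iterrows()
                if r["image_path"] in scored]
        per_sev[band] = {
            "dice": float(np.mean([v[0] for v in vals])) if vals else float("nan"),
            "iou": float(np.mean([v[1] for v in vals])) if vals else float("nan"),
            "n": len(vals),
        }
    return EvalReport(
        mean_dice=float(np.mean(dices)) if dices else float("nan"),
        mean_iou=float(np.mean(ious)) if ious else float("nan"),
        accuracy=accuracy_from_labels(preds, trues) if preds else float("nan"),
        per_severity=per_sev,
        per_class_accuracy={c: float(np.mean(v)) for c, v in sorted(per_class.items())},
        n_images=len(dices), failures=failures)


def predict_batch(model: LeafSam, images: np.ndarray, epoch: int = 0,
                  batch_size: int = 4):
    """Binary masks (threshold 0.5), labels, probabilities, IoU estimates."""
    model.eval()
    masks, labels, probs, ious = [], [], [], []
    with T.no_grad():
        for b0 in range(0, images.shape[0], batch_size):
            out = model(images[b0:b0 + batch_size], epoch=epoch)
            pm = 1.0 / (1.0 + np.exp(-out.mask_logits.data))
            masks.append((pm > 0.5).astype(np.uint8))
            e = np.exp(out.class_logits.data
                       - out.class_logits.data.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            probs.append(p)
            labels.extend(p.argmax(axis=1).tolist())
            ious.extend(out.iou_estimate.data.tolist())
    return np.concatenate(masks), labels, np.concatenate(probs), ious


def evaluate(checkpoint, manifest_path, split: str = "test",
             use_ground_truth: bool = False, epoch: int | None = None) -> EvalReport:
    """Evaluate a checkpoint (or ground-truth masks) on a manifest split.

    ``use_ground_truth=True`` scores the reference masks and labels against
    themselves — the identity sanity path used to validate the severity-
    stratified bookkeeping.
    """
    manifest, root = load_manifest(manifest_path)
    if split:
        manifest = manifest[manifest["split"] == split]
    predictions = {}
    if use_ground_truth:
        for _, row in manifest.iterrows():
            predictions[row["image_path"]] = (
                read_mask_png(root / row["mask_path"]), int(row["label"]))
    else:
        model, meta = (checkpoint, {}) if isinstance(checkpoint, LeafSam) \
            else LeafSam.load(checkpoint)
        if epoch is None:
            epoch = int(meta.get("train", {}).get("epochs", 0))
        images = np.stack([read_image_png(root / r["image_path"])
                           for _, r in manifest.iterrows()])
        masks, labels, _, _ = predict_batch(model, images, epoch=epoch)
        for j, (_, row) in enumerate(manifest.iterrows()):
            predictions[row["image_path"]] = (masks[j], labels[j])
    return evaluate_masks(manifest, root, predictions)


def predict_files(checkpoint, image_paths, out_dir, leaf_mask_paths=None) -> int:
    """Write a binarised mask PNG and a class-probability JSON per image.

    Returns the number of successfully processed images.
    """
    from .losses import poi_severity

    model, meta = (checkpoint, {}) if isinstance(checkpoint, LeafSam) \
        else LeafSam.load(checkpoint)
    epoch = int(meta.get("train", {}).get("epochs", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_ok = 0
    leaf_mask_paths = leaf_mask_paths or {}
    for path in image_paths:
        path = Path(path)
        try:
            img = read_image_png(path)
        except Exception as exc:  # noqa: BLE001
            log.error("skipping %s: %s", path, exc)
            continue
        size = model.cfg.image_size
        if img.shape[1] != size or img.shape[2] != size:
            with T.no_grad():
                img = T.upsample_bilinear(
                    T.as_tensor(img[None]), size).data[0]
        masks, labels, probs, ious = predict_batch(model, img[None], epoch=epoch)
        write_mask_png(out / f"{path.stem}_mask.png", masks[0])
        record = {"class_probabilities": probs[0].tolist(),
                  "label": int(labels[0]), "iou_estimate": float(ious[0])}
        leaf_path = leaf_mask_paths.get(str(path))
        if leaf_path:
            leaf = read_mask_png(leaf_path)
            lesion = (masks[0] & leaf).astype(np.uint8)
            if leaf.sum() and lesion.sum():
                rec = poi_severity(lesion, leaf)
                record["poi"] = rec.poi
                record["severity"] = rec.band
        with open(out / f"{path.stem}.json", "w") as fh:
            json.dump(record, fh, indent=2)
        n_ok += 1
    return n_ok
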