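"""Training and evaluation loops.

The optimizer schedule follows the reference recipe: SGD with momentum 0.9
from an initial learning rate of 0.01, decayed per step with a polynomial
(power 0.9) schedule down to ~0 over the run, batch size 8, and the
0.4·CE + 0.6·Dice compound loss.  Everything is seeded: weight init, data
order, and augmentation draws all derive from TrainConfig.seed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import softmax
from .config import TrainConfig
from .losses import total_loss
from .metrics import evaluate_dataset
from .model import SegModel
from .phantom import MaskPair, augment

__all__ = ["fit", "evaluate_model", "write_runlog_csv"]


def _one_hot(masks: np.ndarray, num_classes: int) -> np.ndarray:
    # (B, H, W) int -> (B, K, H, W) float32
    out = np.zeros((masks.shape[0], num_classes) + masks.shape[1:], dtype=np.float32)
    for c in range(num_classes):
        out[:, c] = masks == c
    return out


def _batch(pairs: list[MaskPair]):
    imgs = np.stack([p.image for p in pairs])[:, None].astype(np.float32)
    masks = np.stack([p.mask for p in pairs]).astype(np.int64)
    return imgs, masks


def fit(model: SegModel, train_pairs: list[MaskPair], cfg: TrainConfig,
        val_pairs: list[MaskPair] | None = None,
        progress: bool = False) -> list[dict]:
    """Train in place; returns the run log (one record per step, plus
    per-epoch summaries carrying mean loss and optional validation Dice)."""
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum)
    n = len(train_pairs)
    steps_per_epoch = max(1, n // cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    K = model.cfg.num_classes
    w = np.asarray(cfg.class_weights, dtype=np.float32)
    log: list[dict] = []
    step = 0
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            batch = [train_pairs[i] for i in idx]
            if cfg.augment != "none":
                # "flip" leaves geometry exact; "flip+crop" adds the random
                # crop/re-resize (blurs boundaries; useful for larger budgets)
                crop = (0.8, 1.0) if cfg.augment == "flip+crop" else (1.0, 1.0)
                batch = [augment(p, seed=int(rng.integers(2 ** 31)),
                                 crop_frac=crop)
                         for p in batch]
            imgs, masks = _batch(batch)
            lr = cfg.lr_at(step, total_steps)
            opt.lr = lr
            logits = model(imgs)
            probs = softmax(logits, axis=1)
            loss = total_loss(probs, _one_hot(masks, K), w, class_axis=1,
                              ce_weight=cfg.ce_weight,
                              dice_weight=cfg.dice_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            val = float(loss.data)
            epoch_losses.append(val)
            log.append({"kind": "step", "epoch": epoch, "step": step,
                        "lr": lr, "loss": val})
            step += 1
        rec = {"kind": "epoch", "epoch": epoch, "step": step,
               "lr": cfg.lr_at(step, total_steps),
               "loss": float(np.mean(epoch_losses))}
        if val_pairs:
            model.eval()
            _, agg = evaluate_model(model, val_pairs)
            model.train()
            rec["val_dice"] = agg["dice"]
        log.append(rec)
        if progress:
            msg = f"epoch {epoch + 1}/{cfg.epochs}  loss {rec['loss']:.4f}"
            if "val_dice" in rec:
                msg += f"  val dice {rec['val_dice']:.4f}"
            print(msg, flush=True)
    model.eval()
    return log


def evaluate_model(model: SegModel, pairs: list[MaskPair],
                   spacing: float = 1.0, batch_size: int = 8):
    """Per-image and aggregate Dice/HD95/Precision/Recall on a split."""
    model.eval()
    preds = []
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i:i + batch_size]
        imgs, _ = _batch(chunk)
        preds.extend(model.predict_mask(imgs))
    return evaluate_dataset(
        [(pred, pair.mask) for pred, pair in zip(preds, pairs)], spacing)


def write_runlog_csv(path, log: list[dict]):
    fields = ["kind", "epoch", "step", "lr", "loss", "val_dice"]
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in log:
            writer.writerow({k: rec.get(k, "") for k in fields})
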