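"""Segmentation evaluation: confusion counts, Dice / Precision / Recall,
and the 95th-percentile symmetric Hausdorff boundary distance (HD95).

Conventions (documented because degenerate masks occur in practice):

* Dice = 2TP / (2TP + FP + FN); when both masks are empty all three ratios
  are defined as 1; an empty prediction against a non-empty truth (or vice
  versa) scores 0.
* HD95 boundaries are the 8-connected boundary pixels of each mask
  (mask minus its erosion by the 3×3 cross); each directed set of
  nearest-neighbour distances is reduced at the 95th percentile with
  linear interpolation, and the symmetric value is the max of the two
  directions.  Distances are in pixel units unless a `spacing` (isotropic
  pixel size) is supplied.  HD95 is undefined for an empty boundary set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = ["ConfusionCounts", "confusion", "dice_precision_recall",
           "boundary_points", "hd95", "evaluate_pair", "evaluate_dataset",
           "write_metrics_csv"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _check_binary(mask, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool and not np.isin(np.unique(m), (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), got values "
                         f"{np.unique(m)[:5]}")
    return m.astype(bool)


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN tallies for two binary masks of equal shape."""
    p = _check_binary(pred_mask, "prediction")
    g = _check_binary(true_mask, "ground truth")
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def dice_precision_recall(c: ConfusionCounts) -> tuple[float, float, float]:
    """(Dice, Precision, Recall) from confusion counts, with the empty-mask
    conventions stated in the module docstring."""
    if c.TP == 0 and c.FP == 0 and c.FN == 0:
        return 1.0, 1.0, 1.0
    dice = 2 * c.TP / (2 * c.TP + c.FP + c.FN)
    pre = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    rec = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    return dice, pre, rec


def boundary_points(mask) -> np.ndarray:
    """(n, 2) coordinates of the 8-connected boundary of a binary mask
    (foreground pixels removed by a 3×3-cross erosion; image-border
    foreground counts as boundary)."""
    m = _check_binary(mask, "mask")
    if m.ndim != 2:
        raise ValueError("boundary extraction expects a 2-D mask")
    boundary = m & ~binary_erosion(m)
    return np.argwhere(boundary)


def hd95(a_points, b_points, spacing: float = 1.0) -> float:
    """Symmetric 95th-percentile Hausdorff distance between two point sets.

    Raises ValueError on an empty set (the distance is undefined there).
    """
    A = np.asarray(a_points, dtype=float)
    B = np.asarray(b_points, dtype=float)
    if A.size == 0 or B.size == 0:
        raise ValueError("HD95 is undefined for an empty boundary set")
    d_ab = cKDTree(B).query(A, k=1)[0]
    d_ba = cKDTree(A).query(B, k=1)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))) * spacing


def evaluate_pair(pred_mask, true_mask, spacing: float = 1.0) -> dict:
    """Dice/HD95/Precision/Recall for one prediction/label pair.

    HD95 is NaN when either mask has no boundary (empty mask); aggregation
    ignores NaNs.
    """
    c = confusion(pred_mask, true_mask)
    dice, pre, rec = dice_precision_recall(c)
    pa = boundary_points(pred_mask)
    pb = boundary_points(true_mask)
    hd = hd95(pa, pb, spacing) if len(pa) and len(pb) else float("nan")
    return {"dice": dice, "hd95": hd, "precision": pre, "recall": rec}


def evaluate_dataset(pairs, spacing: float = 1.0) -> tuple[list[dict], dict]:
    """Per-image metric rows plus the aggregate mean (NaN-aware for HD95)."""
    rows = [evaluate_pair(p, g, spacing) for p, g in pairs]
    if not rows:
        raise ValueError("no prediction/label pairs supplied")
    agg = {}
    for key in ("dice", "hd95", "precision", "recall"):
        vals = np.array([r[key] for r in rows], dtype=float)
        agg[key] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return rows, agg


def write_metrics_csv(path, rows: list[dict], agg: dict | None = None):
    path = Path(path)
    fields = ["id", "dice", "hd95", "precision", "recall"]
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for i, r in enumerate(rows):
            writer.writerow({"id": r.get("id", i), **{k: r[k] for k in fields[1:]}})
        if agg is not None:
            writer.writerow({"id": "mean", **{k: agg[k] for k in fields[1:]}})
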