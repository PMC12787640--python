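"""Compound segmentation loss: weighted cross-entropy + weighted soft Dice.

    L_wce  = −(1/N) Σ_i Σ_c w_c g_{i,c} ln p_{i,c}
    L_wdice = 1 − Σ_c 2 w_c (Σ_i p_{i,c} g_{i,c}) / (Σ_i p²_{i,c} + Σ_i g²_{i,c})
    L      = 0.4 · L_wce + 0.6 · L_wdice

with class weights w_c > 0 normalised to Σ w_c = 1 by default, so a perfect
one-hot prediction drives both terms to zero.  All three functions accept
NumPy arrays (returning floats) or autodiff Tensors (returning a Tensor on
the tape, for training).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["weighted_ce", "weighted_dice_loss", "total_loss"]

EPS = 1e-7


def _prep(p, g, w, class_axis):
    """Move the class axis last and flatten pixels; validate shapes."""
    wrap = isinstance(p, Tensor) or isinstance(g, Tensor)
    pt = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float32))
    gt = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=np.float32))
    if pt.shape != gt.shape:
        raise ValueError(f"prediction/label shape mismatch: {pt.shape} vs {gt.shape}")
    C = pt.shape[class_axis]
    w = np.asarray(w, dtype=np.float32)
    if w.shape != (C,):
        raise ValueError(f"need one weight per class, got {w.shape} for C={C}")
    axes = tuple(i for i in range(pt.ndim) if i != (class_axis % pt.ndim))
    perm = axes + (class_axis % pt.ndim,)
    if pt.ndim == 1:
        pt, gt = pt.reshape(1, C), gt.reshape(1, C)
    else:
        pt = pt.transpose(perm).reshape(-1, C)
        gt = gt.transpose(perm).reshape(-1, C)
    return pt, gt, Tensor(w), wrap


def _ret(value: Tensor, wrap: bool):
    return value if wrap else float(value.data)


def weighted_ce(p, g, w=(0.5, 0.5), *, class_axis: int = 0, eps: float = EPS):
    """Class-weighted cross entropy averaged over pixels.

    `p` holds per-pixel class probabilities, `g` the one-hot ground truth;
    probabilities are kept away from zero by `eps` before the log.
    """
    pt, gt, wt, wrap = _prep(p, g, w, class_axis)
    n = pt.shape[0]
    ll = (pt + eps).log() * gt * wt
    return _ret(-(ll.sum() * (1.0 / n)), wrap)


def weighted_dice_loss(p, g, w=(0.5, 0.5), *, class_axis: int = 0,
                       eps: float = EPS):
    """1 − Σ_c 2 w_c ⟨p,g⟩_c / (‖p‖²_c + ‖g‖²_c), the soft-Dice compound.

    With Σ w_c = 1 the loss lies in [0, 1] and vanishes only for a perfect
    prediction; `eps` guards all-empty classes in the denominator.
    """
    pt, gt, wt, wrap = _prep(p, g, w, class_axis)
    inter = (pt * gt).sum(axis=0)
    denom = (pt * pt).sum(axis=0) + (gt * gt).sum(axis=0) + eps
    dice = (wt * 2.0 * inter / denom).sum()
    return _ret(1.0 - dice, wrap)


def total_loss(p, g, w=(0.5, 0.5), *, class_axis: int = 0,
               ce_weight: float = 0.4, dice_weight: float = 0.6,
               eps: float = EPS):
    """The 0.4·CE + 0.6·Dice training objective."""
    ce = weighted_ce(p, g, w, class_axis=class_axis, eps=eps)
    dl = weighted_dice_loss(p, g, w, class_axis=class_axis, eps=eps)
    return ce * ce_weight + dl * dice_weight if isinstance(ce, Tensor) \
        else ce_weight * ce + dice_weight * dl
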