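"""Visual state-space encoder: grayscale → patch embedding → four stages of
VSS blocks with patch-merging downsampling.

Stage s emits a map of size (H/2^{s+1}) × (W/2^{s+1}) with C·2^{s-1}
channels, i.e. the H/4…H/32, C…8C hierarchy.  Tokens are channel-last
internally; stage outputs are returned channel-first (NCHW) at the module
boundary.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .ssm import SS2D

__all__ = ["grayscale", "PatchEmbed", "VSSBlock", "PatchMerging", "Encoder"]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float32)


def grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an H×W×3 RGB image to single-channel luminance (BT.601).

    Values stay inside the input range because the weights sum to 1.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected H×W×3 RGB input, got shape {image.shape}")
    return image @ _LUMA


class PatchEmbed(nn.Module):
    """Non-overlapping 4×4 patches flattened to 16-vectors, then linearly
    embedded to `dim` channels with a LayerNorm."""

    def __init__(self, dim: int, in_ch: int = 1):
        super().__init__()
        self.dim = dim
        self.in_ch = in_ch
        self.proj = nn.Linear(16 * in_ch, dim)
        self.norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, in_ch, H, W) -> tokens (B, H/4, W/4, dim)
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channel(s), got {C}")
        if H % 4 or W % 4:
            raise ValueError(f"spatial dims must be divisible by 4, got {H}×{W}")
        h, w = H // 4, W // 4
        t = x.reshape(B, C, h, 4, w, 4).transpose(0, 2, 4, 3, 5, 1)
        t = t.reshape(B, h, w, 16 * C)
        return self.norm(self.proj(t))


class VSSBlock(nn.Module):
    """The visual state-space block (LN → linear expand → two branches).

    Branch 1: depthwise 3×3 conv → SiLU → SS2D → LN; branch 2: linear →
    SiLU.  The branches merge by elementwise product (the gating of the
    VMamba design), then a linear layer projects back and a residual adds
    the input.  Token layout (B, H, W, C).
    """

    def __init__(self, dim: int, d_state: int = 16, expand: int = 1):
        super().__init__()
        self.dim = dim
        d_inner = dim * expand
        self.norm = nn.LayerNorm(dim)
        self.in_proj = nn.Linear(dim, d_inner)
        self.gate_proj = nn.Linear(dim, d_inner)
        self.dwconv = nn.Conv2d(d_inner, d_inner, 3, padding=1, groups=d_inner)
        # Δ-projection rank follows the Mamba "auto" rule on the block dim
        self.ss2d = SS2D(d_inner, d_state=d_state, dt_rank=max(1, dim // 16))
        self.out_norm = nn.LayerNorm(d_inner)
        self.out_proj = nn.Linear(d_inner, dim)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if C != self.dim:
            raise ValueError(f"block built for {self.dim} channels, got {C}")
        xn = self.norm(x)
        a = self.in_proj(xn)
        # depthwise conv runs channel-first
        a = self.dwconv(a.transpose(0, 3, 1, 2)).transpose(0, 2, 3, 1)
        a = self.out_norm(self.ss2d(a.silu()))
        b = self.gate_proj(xn).silu()
        return x + self.out_proj(a * b)


class PatchMerging(nn.Module):
    """2×2 neighbourhood concatenation (4C) → LayerNorm → linear to 2C."""

    def __init__(self, dim: int):
        super().__init__()
        self.dim = dim
        self.norm = nn.LayerNorm(4 * dim)
        self.reduction = nn.Linear(4 * dim, 2 * dim, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"patch merging needs even dims, got {H}×{W}")
        parts = [x[:, 0::2, 0::2, :], x[:, 1::2, 0::2, :],
                 x[:, 0::2, 1::2, :], x[:, 1::2, 1::2, :]]
        t = concat(parts, axis=-1)
        return self.reduction(self.norm(t))


class Encoder(nn.Module):
    """Four-stage VSS encoder producing the C…8C pyramid.

    `depths` gives the VSS-block count per stage; channels double and the
    spatial dims halve between consecutive stages.
    """

    def __init__(self, base_channels: int = 96, depths=(2, 2, 9, 2),
                 d_state: int = 16, expand: int = 1, in_ch: int = 1):
        super().__init__()
        self.base_channels = base_channels
        self.depths = tuple(depths)
        self.patch_embed = PatchEmbed(base_channels, in_ch=in_ch)
        self.stages = nn.ModuleList()
        self.merges = nn.ModuleList()
        dim = base_channels
        for s, depth in enumerate(self.depths):
            self.stages.append(nn.ModuleList(
                [VSSBlock(dim, d_state=d_state, expand=expand)
                 for _ in range(depth)]))
            if s < len(self.depths) - 1:
                self.merges.append(PatchMerging(dim))
                dim *= 2

    def load_pretrained(self, path) -> list[str]:
        """Best-effort import of encoder weights from a flat name→array
        .npz archive (e.g. an externally trained backbone).  Arrays are
        matched by parameter name and shape; everything else is left at
        its initialisation.  Returns the names actually loaded."""
        with np.load(path, allow_pickle=False) as npz:
            archive = {k: npz[k] for k in npz.files}
        loaded = []
        for name, p in self.named_parameters():
            arr = archive.get(name)
            if arr is not None and arr.shape == p.data.shape:
                p.data[...] = arr
                loaded.append(name)
        return loaded

    def forward(self, x: Tensor) -> list[Tensor]:
        B, C, H, W = x.shape
        if H % 32 or W % 32:
            raise ValueError(f"input dims must be divisible by 32, got {H}×{W}")
        t = self.patch_embed(x)
        outs: list[Tensor] = []
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                t = blk(t)
            outs.append(t.transpose(0, 3, 1, 2))  # NCHW at the boundary
            if s < len(self.merges):
                t = self.merges[s](t)
        return outs
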