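"""Cross-Fusion Module for skip connections.

Given the encoder map X_E and decoder map X_D at the same resolution:

  1. fuse:        X_E1 = ReLU(BN(Conv3×3(concat(X_E, X_D))))   (2C → C)
  2. cross-attn:  queries from X_D, keys/values from X_E1, multi-head
                  scaled dot-product over the row-major token flattening,
                  heads concatenated and projected by W_O (no biases);
  3. residuals:   R = AM + X_D;  X_F = R + FFN(R) with
                  FFN(x) = max(0, x W1 + b1) W2 + b2.

Output shape equals the input shape, so a zero-weight CFM degrades to the
identity on X_D.
"""

from __future__ import annotations

import math

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, concat, softmax

__all__ = ["CrossAttention", "CFM"]


class CrossAttention(nn.Module):
    """Multi-head scaled dot-product attention with separate query and
    key/value token sets (both (B, L, C))."""

    def __init__(self, dim: int, heads: int = 8):
        super().__init__()
        if dim % heads:
            raise ValueError(f"head count {heads} must divide channels {dim}")
        self.dim, self.heads, self.dk = dim, heads, dim // heads
        self.wq = nn.Linear(dim, dim, bias=False)
        self.wk = nn.Linear(dim, dim, bias=False)
        self.wv = nn.Linear(dim, dim, bias=False)
        self.wo = nn.Linear(dim, dim, bias=False)

    def _split(self, t: Tensor) -> Tensor:
        B, L, C = t.shape
        return t.reshape(B, L, self.heads, self.dk).transpose(0, 2, 1, 3)

    def forward(self, queries: Tensor, context: Tensor) -> Tensor:
        if queries.shape != context.shape:
            raise ValueError("query and context token sets must share (B, L, C)")
        B, L, C = queries.shape
        q = self._split(self.wq(queries))
        k = self._split(self.wk(context))
        v = self._split(self.wv(context))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dk))
        att = softmax(logits, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, C)
        return self.wo(out)


class CFM(nn.Module):
    def __init__(self, dim: int, heads: int = 8, ffn_ratio: int = 4):
        super().__init__()
        self.dim = dim
        self.fuse_conv = nn.Conv2d(2 * dim, dim, 3, padding=1)
        self.fuse_bn = nn.BatchNorm2d(dim)
        self.attn = CrossAttention(dim, heads)
        self.ffn_fc1 = nn.Linear(dim, ffn_ratio * dim)
        self.ffn_fc2 = nn.Linear(ffn_ratio * dim, dim)

    def fuse(self, xe: Tensor, xd: Tensor) -> Tensor:
        if xe.shape != xd.shape:
            raise ValueError(f"encoder/decoder maps must match, "
                             f"got {xe.shape} vs {xd.shape}")
        return self.fuse_bn(self.fuse_conv(concat([xe, xd], axis=1))).relu()

    def ffn(self, x: Tensor) -> Tensor:
        return self.ffn_fc2(self.ffn_fc1(x).relu())

    def forward(self, xe: Tensor, xd: Tensor) -> Tensor:
        B, C, H, W = xd.shape
        xe1 = self.fuse(xe, xd)
        # row-major tokenization at the skip's native resolution
        tok_d = xd.reshape(B, C, H * W).transpose(0, 2, 1)
        tok_e = xe1.reshape(B, C, H * W).transpose(0, 2, 1)
        am = self.attn(tok_d, tok_e)
        r = am + tok_d
        xf = r + self.ffn(r)
        return xf.transpose(0, 2, 1).reshape(B, C, H, W)
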