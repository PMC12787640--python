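"""Hybrid Attention Enhancement Mechanism (bottleneck module).

Two branches over the deepest encoder map F (C×H×W):

* channel attention  M_C = BN( MLP(avgpool F) + MLP(maxpool F) ), with a
  shared two-layer MLP (C → C/r → C, ReLU in between);
* spatial attention  M_S = BN( 1×1 → 3×3 dilated → 3×3 dilated → 1×1 (F) ).

The branch maps broadcast-sum to S = M_C + M_S; a depthwise 3×3 conv plus
residual and a sigmoid give the hybrid gate M_H = σ(DWConv(S) + S) ∈ (0,1),
and the output is F_O = F + M_H ⊗ F, so each entry of F is scaled by a
factor in (1, 2).
"""

from __future__ import annotations

from . import nn
from .autodiff import Tensor

__all__ = ["ChannelAttention", "SpatialAttention", "HAEM"]


class ChannelAttention(nn.Module):
    def __init__(self, channels: int, r: int = 16):
        super().__init__()
        if channels % r:
            raise ValueError(f"reduction ratio {r} must divide channels {channels}")
        self.channels = channels
        self.fc0 = nn.Linear(channels, channels // r)
        self.fc1 = nn.Linear(channels // r, channels)
        self.bn = nn.BatchNorm2d(channels)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc1(self.fc0(v).relu())

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)
        avg = flat.mean(axis=2)
        mx = flat.amax(axis=2)
        s = self._mlp(avg) + self._mlp(mx)          # (B, C)
        return self.bn(s.reshape(B, C, 1, 1))


class SpatialAttention(nn.Module):
    """1×1 reduce → two 3×3 dilated convs (same padding) → 1×1 collapse → BN."""

    def __init__(self, channels: int, r: int = 16, dilation: int = 4):
        super().__init__()
        if channels % r:
            raise ValueError(f"reduction ratio {r} must divide channels {channels}")
        mid = channels // r
        self.reduce = nn.Conv2d(channels, mid, 1)
        self.dconv1 = nn.Conv2d(mid, mid, 3, padding=dilation, dilation=dilation)
        self.dconv2 = nn.Conv2d(mid, mid, 3, padding=dilation, dilation=dilation)
        self.collapse = nn.Conv2d(mid, 1, 1)
        self.bn = nn.BatchNorm2d(1)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.collapse(self.dconv2(self.dconv1(self.reduce(x)))))


class HAEM(nn.Module):
    def __init__(self, channels: int, r: int = 16, dilation: int = 4):
        super().__init__()
        self.channels = channels
        self.channel_att = ChannelAttention(channels, r)
        self.spatial_att = SpatialAttention(channels, r, dilation)
        self.dwconv = nn.Conv2d(channels, channels, 3, padding=1, groups=channels)

    def attention_map(self, x: Tensor) -> Tensor:
        """The hybrid gate M_H ∈ (0,1)^{C×H×W}."""
        s = self.channel_att(x) + self.spatial_att(x)   # broadcast C×1×1 + 1×H×W
        return (self.dwconv(s) + s).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        mh = self.attention_map(x)
        return x + mh * x

    def set_bn_identity(self):
        self.channel_att.bn.set_identity()
        self.spatial_att.bn.set_identity()
        return self
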