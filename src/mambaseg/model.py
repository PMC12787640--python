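"""Full segmentation network and its complexity accounting.

Assembly (U-shape): VSS encoder → HAEM on the deepest (8C) map → three
decoder levels, each a kernel-2/stride-2 transposed convolution (halving
channels, doubling resolution) followed by cross-fusion with the matching
encoder stage → 1×1 projection to class logits and 4× bilinear upsampling
back to the input resolution.

Complexity is reported two ways: the parameter count is the exact sum over
learnable arrays; FLOPs are counted analytically with the 2×MAC convention
(each multiply-accumulate in a conv/linear/attention/scan counts as two
floating-point operations; normalisations and activations are not counted).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .cfm import CFM
from .config import ModelConfig
from .encoder import Encoder, grayscale
from .haem import HAEM

__all__ = ["SegModel", "build_model", "count_complexity", "flops_breakdown",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = "mambaseg-ckpt-1"


class SegModel(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        C = cfg.base_channels
        self.encoder = Encoder(C, cfg.stage_depths, d_state=cfg.ssm_state_dim,
                               expand=cfg.ssm_expand, in_ch=cfg.in_channels)
        self.haem = HAEM(8 * C, r=cfg.haem_r, dilation=cfg.haem_dilation)
        self.up3 = nn.ConvTranspose2d(8 * C, 4 * C)
        self.up2 = nn.ConvTranspose2d(4 * C, 2 * C)
        self.up1 = nn.ConvTranspose2d(2 * C, C)
        # CFM-3 fuses every skip; CFM-1 only the deepest, the rest add
        self.cfm3 = CFM(4 * C, cfg.cfm_heads, cfg.cfm_ffn_ratio)
        if cfg.cfm_levels == 3:
            self.cfm2 = CFM(2 * C, cfg.cfm_heads, cfg.cfm_ffn_ratio)
            self.cfm1 = CFM(C, cfg.cfm_heads, cfg.cfm_ffn_ratio)
        # 1×1 projection to class logits at stride 4, then 4× bilinear
        # upsampling in forward (a learned patch-expanding head trains
        # slower and segments worse at desk scale; see docs/methods.md)
        self.head = nn.Conv2d(C, cfg.num_classes, 1)

    def _prepare(self, image) -> Tensor:
        """Accept (B,1,H,W) or (B,3,H,W) arrays/tensors; RGB is grayscaled."""
        x = image.data if isinstance(image, Tensor) else np.asarray(
            image, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError(f"expected a batched NCHW image, got shape {x.shape}")
        if x.shape[1] == 3:
            gray = np.stack([grayscale(im.transpose(1, 2, 0)) for im in x])
            x = gray[:, None]
        elif x.shape[1] != 1:
            raise ValueError(f"expected 1 or 3 channels, got {x.shape[1]}")
        return Tensor(x)

    def forward(self, image) -> Tensor:
        x = self._prepare(image)
        s1, s2, s3, s4 = self.encoder(x)
        d = self.haem(s4)                       # dims unchanged at bottleneck
        d = self.up3(d)
        d = self.cfm3(s3, d)
        d = self.up2(d)
        d = self.cfm2(s2, d) if self.cfg.cfm_levels == 3 else d + s2
        d = self.up1(d)
        d = self.cfm1(s1, d) if self.cfg.cfm_levels == 3 else d + s1
        return ad.upsample_bilinear(self.head(d), 4)

    def predict_proba(self, image) -> np.ndarray:
        """Class probabilities (B, K, H, W), no graph recorded."""
        with ad.no_grad():
            logits = self.forward(image)
        return ad.softmax(logits, axis=1).data

    def predict_mask(self, image) -> np.ndarray:
        """Hard foreground masks (B, H, W) ∈ {0,1} (class 1 = lesion)."""
        p = self.predict_proba(image)
        return (p[:, 1] > p[:, 0]).astype(np.uint8)


def build_model(cfg: ModelConfig, seed: int | None = None) -> SegModel:
    if seed is not None:
        nn.set_init_seed(seed)
    return SegModel(cfg)


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

def flops_breakdown(cfg: ModelConfig) -> dict[str, float]:
    """Analytic forward-pass FLOPs per component at cfg.input_size.

    Convention: 2 FLOPs per multiply-accumulate in convolutions, linear
    layers, attention matmuls and the scan recurrence (6 per token/channel/
    state for the three-term recurrence plus output contraction); element-
    wise activations and normalisations are excluded.
    """
    H, W = cfg.input_size
    C = cfg.base_channels
    E, N = cfg.ssm_expand, cfg.ssm_state_dim
    fl: dict[str, float] = {}

    def vss_block(d: int, L: int) -> float:
        di = d * E
        R = max(1, d // 16)
        f = 2 * L * d * di * 3              # in/gate/out projections
        f += 2 * L * 9 * di                 # depthwise 3×3
        per_dir = 2 * L * di * (R + 2 * N)  # x_proj
        per_dir += 2 * L * R * di           # dt_proj
        per_dir += 6 * L * di * N           # recurrence + output contraction
        per_dir += 2 * L * di               # D skip
        return f + 4 * per_dir

    h, w = H // 4, W // 4
    fl["patch_embed"] = 2 * h * w * 16 * cfg.in_channels * C
    dims = cfg.stage_channels
    for s, depth in enumerate(cfg.stage_depths):
        d = dims[s]
        L = (H // (4 * 2 ** s)) * (W // (4 * 2 ** s))
        fl[f"encoder_stage{s + 1}"] = depth * vss_block(d, L)
        if s < 3:
            fl[f"patch_merge{s + 1}"] = 2 * (L // 4) * (4 * d) * (2 * d)

    # HAEM at the bottleneck (8C, H/32 × W/32)
    c8 = dims[3]
    L4 = (H // 32) * (W // 32)
    r = cfg.haem_r
    fl["haem"] = (2 * 2 * 2 * c8 * (c8 // r)            # shared MLP, two pools
                  + 2 * L4 * c8 * (c8 // r)             # 1×1 reduce
                  + 2 * 2 * L4 * 9 * (c8 // r) ** 2     # two dilated 3×3
                  + 2 * L4 * (c8 // r)                  # 1×1 collapse
                  + 2 * L4 * 9 * c8)                    # depthwise 3×3

    def cfm(dch: int, L: int) -> float:
        f = 2 * L * 9 * (2 * dch) * dch                 # fuse conv
        f += 4 * 2 * L * dch * dch                      # Q,K,V,O projections
        f += 2 * 2 * L * L * dch                        # QKᵀ and AV
        f += 2 * 2 * L * dch * (cfg.cfm_ffn_ratio * dch)  # FFN
        return f

    skip_dims = [(dims[2], (H // 16) * (W // 16)),
                 (dims[1], (H // 8) * (W // 8)),
                 (dims[0], (H // 4) * (W // 4))]
    # transposed convs: each output pixel touches exactly one 2×2 tap
    fl["upsample3"] = 2 * skip_dims[0][1] * dims[3] * dims[2]
    fl["upsample2"] = 2 * skip_dims[1][1] * dims[2] * dims[1]
    fl["upsample1"] = 2 * skip_dims[2][1] * dims[1] * dims[0]
    fl["cfm3"] = cfm(*skip_dims[0])
    if cfg.cfm_levels == 3:
        fl["cfm2"] = cfm(*skip_dims[1])
        fl["cfm1"] = cfm(*skip_dims[2])
    fl["head"] = 2 * (H // 4) * (W // 4) * C * cfg.num_classes
    fl["final_upsample"] = 8 * H * W * cfg.num_classes
    return fl


def count_complexity(cfg: ModelConfig,
                     model: SegModel | None = None) -> tuple[float, float]:
    """(parameters in millions, forward FLOPs in giga) for one pass at
    cfg.input_size."""
    if model is None:
        model = build_model(cfg, seed=0)
    params_m = model.num_parameters() / 1e6
    flops_g = sum(flops_breakdown(cfg).values()) / 1e9
    return params_m, flops_g


# ---------------------------------------------------------------------------
# checkpoint I/O (flat name→array archive)
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SegModel):
    state = {"__version__": np.array(CHECKPOINT_VERSION)}
    state.update(model.state_dict())
    np.savez(Path(path), **state)


def load_checkpoint(path, model: SegModel):
    with np.load(Path(path), allow_pickle=False) as npz:
        state = {k: npz[k] for k in npz.files}
    version = str(state.pop("__version__", ""))
    if version != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {version!r}")
    model.load_state_dict(state)
    return model
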