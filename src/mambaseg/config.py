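"""Run configuration: model architecture and training hyperparameters.

Two named profiles are provided: ``full`` is the publication-scale network
(C=96, depths [2,2,9,2], 224×224 input); ``tiny`` is the desk-scale profile
used throughout the test-suite and smoke training (C=32, depths [1,1,2,1],
64×64 input, r=2, 2 attention heads).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "TrainConfig", "PROFILES", "load_config", "save_config"]


@dataclass
class ModelConfig:
    base_channels: int = 96
    stage_depths: tuple[int, ...] = (2, 2, 9, 2)
    ssm_state_dim: int = 16
    ssm_expand: int = 2
    haem_r: int = 16
    haem_dilation: int = 4
    cfm_heads: int = 8
    cfm_ffn_ratio: int = 4
    cfm_levels: int = 3
    num_classes: int = 2
    input_size: tuple[int, int] = (224, 224)
    in_channels: int = 1

    def __post_init__(self):
        self.stage_depths = tuple(self.stage_depths)
        self.input_size = tuple(self.input_size)
        H, W = self.input_size
        if H % 32 or W % 32:
            raise ValueError(f"input size must be divisible by 32, got {H}×{W}")
        if len(self.stage_depths) != 4 or any(d < 1 for d in self.stage_depths):
            raise ValueError("stage_depths must be four positive integers")
        if (8 * self.base_channels) % self.haem_r:
            raise ValueError("haem_r must divide the bottleneck channel count")
        if self.cfm_levels not in (1, 3):
            raise ValueError("cfm_levels must be 1 or 3")
        for c in (4, 2, 1):
            if (c * self.base_channels) % self.cfm_heads:
                raise ValueError("cfm_heads must divide every skip channel count")

    @property
    def stage_channels(self) -> tuple[int, ...]:
        C = self.base_channels
        return (C, 2 * C, 4 * C, 8 * C)


@dataclass
class TrainConfig:
    lr0: float = 0.01
    momentum: float = 0.9
    batch_size: int = 8
    epochs: int = 300
    poly_power: float = 0.9
    class_weights: tuple[float, float] = (0.5, 0.5)
    ce_weight: float = 0.4
    dice_weight: float = 0.6
    seed: int = 0
    augment: str = "flip"            # none | flip | flip+crop

    def __post_init__(self):
        self.class_weights = tuple(self.class_weights)
        if self.lr0 <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("training hyperparameters must be positive")
        if self.augment not in ("none", "flip", "flip+crop"):
            raise ValueError(f"unknown augmentation policy {self.augment!r}")

    def lr_at(self, step: int, total_steps: int) -> float:
        """Polynomial decay lr0·(1 − step/total)^power (monotone to ~0)."""
        frac = min(step / max(total_steps, 1), 1.0)
        return self.lr0 * (1.0 - frac) ** self.poly_power


PROFILES: dict[str, ModelConfig] = {
    "full": ModelConfig(),
    "tiny": ModelConfig(base_channels=32, stage_depths=(1, 1, 2, 1),
                        ssm_expand=1, haem_r=2, cfm_heads=2,
                        input_size=(64, 64)),
}


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def save_config(path, model_cfg: ModelConfig, train_cfg: TrainConfig | None = None):
    doc = {"model": _to_dict(model_cfg)}
    if train_cfg is not None:
        doc["train"] = _to_dict(train_cfg)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> tuple[ModelConfig, TrainConfig]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    model_cfg = ModelConfig(**doc.get("model", {}))
    train_cfg = TrainConfig(**doc.get("train", {}))
    return model_cfg, train_cfg
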