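"""Architecture and training hyperparameter containers.

Every knob the network leaves open is surfaced here; YAML round-tripping
makes resolved configurations archivable alongside checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "TrainConfig"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the two-stream fusion network.

    The encoder is a six-stage backbone (stride per stage in
    ``stage_strides``) run once per modality.  Cross-modality feature
    supplementation (CFS) acts in ``cfs_stages`` (1-based); the top stages
    are weight-shared between the branches when ``share_high_stages``.
    """

    stage_channels: tuple[int, ...] = (16, 24, 40, 80, 160, 160)
    stage_strides: tuple[int, ...] = (2, 2, 2, 2, 2, 1)
    cfs_stages: tuple[int, ...] = (1, 2, 3, 4)
    ff_channels: tuple[int, ...] | None = None   # None -> stage_channels
    bam_reduction: int = 16
    bam_dilation: int = 4
    share_high_stages: bool = True
    depth_input_mode: str = "replicate3"         # or "learned1to3"
    decoder_width: int = 64
    rfb_dilations: tuple[int, ...] = (1, 3, 5)
    cff_high_uses_prev: bool = False
    fusion_scheme: str = "cff"                   # addition | max | concatenation | cff
    head_hidden: int = 128

    def __post_init__(self):
        if len(self.stage_channels) != 6 or len(self.stage_strides) != 6:
            raise ValueError("backbone must have exactly six stages")
        if any(s < 1 or s > 6 for s in self.cfs_stages):
            raise ValueError("cfs_stages must be within 1..6")
        if self.fusion_scheme not in ("cff", "addition", "max", "concatenation"):
            raise ValueError(f"unknown fusion_scheme {self.fusion_scheme!r}")
        if self.depth_input_mode not in ("replicate3", "learned1to3"):
            raise ValueError(f"unknown depth_input_mode {self.depth_input_mode!r}")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Width-reduced preset for CPU-scale experiments."""
        base = dict(stage_channels=(8, 12, 16, 24, 32, 32), bam_reduction=4,
                    bam_dilation=2, decoder_width=16, head_hidden=32)
        base.update(overrides)
        return cls(**base)

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("stage_channels", "stage_strides", "cfs_stages",
                    "ff_channels", "rfb_dilations"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: AdamW at a constant learning rate."""

    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 0.05
    optimizer: str = "adamw"
    seed: int = 0
    device: str = "cpu"
    input_size: int = 224
    augment: str = "flips"        # none | flips | full
    loss: str = "l1"              # l1 | smooth_l1 | l2
    normalize_targets: bool = False
    eval_every: int = 1
    keep_best: bool = True   # restore the best-validation-MAE parameters

    def __post_init__(self):
        if self.optimizer != "adamw":
            raise ValueError("only adamw is supported")
        if self.loss not in ("l1", "smooth_l1", "l2"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.augment not in ("none", "flips", "full"):
            raise ValueError(f"unknown augment mode {self.augment!r}")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
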