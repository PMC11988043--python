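"""Complete weight-estimation models.

``WeightNet`` is the full two-stream encoder / CFF decoder / regression
pipeline.  The remaining classes are the comparison topologies: a
single-modality backbone regressor, early fusion (depth stacked as a
fourth input channel into one backbone), and late fusion (independent
backbones whose final pooled features are concatenated).
"""

from __future__ import annotations

from . import nn
from .config import ModelConfig
from .decoder import Decoder
from .encoder import BackboneStage, TwoStreamEncoder
from .nn import Tensor
from .regression import RegressionHead

__all__ = ["WeightNet", "SingleStreamNet", "EarlyFusionNet", "LateFusionNet",
           "build_model"]


class WeightNet(nn.Module):
    """Two-stream bidirectional interaction network (multi-scale fusion)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.encoder = TwoStreamEncoder(config)
        self.decoder = Decoder(config)
        self.head = RegressionHead(self.decoder.out_channels, config.head_hidden)

    def forward(self, rgb: Tensor, depth: Tensor) -> Tensor:
        pyr_r, pyr_d = self.encoder(rgb, depth)
        fused = self.decoder(pyr_r, pyr_d)
        return self.head(fused)


class _Backbone(nn.Module):
    """Plain six-stage single stack (no cross-modal interaction)."""

    def __init__(self, config: ModelConfig, in_channels: int):
        super().__init__()
        ch = config.stage_channels
        ins = (in_channels,) + ch[:-1]
        self.stages = nn.ModuleList(
            BackboneStage(ins[i], ch[i], config.stage_strides[i])
            for i in range(6))
        self.out_channels = ch[-1]

    def forward(self, x: Tensor) -> Tensor:
        for stage in self.stages:
            x = stage(x)
        return x


class SingleStreamNet(nn.Module):
    """One-modality baseline: backbone + regression head."""

    def __init__(self, config: ModelConfig, modality: str):
        super().__init__()
        if modality not in ("rgb", "depth"):
            raise ValueError(f"modality must be rgb or depth, got {modality!r}")
        self.modality = modality
        self.backbone = _Backbone(config, 3)
        self.head = RegressionHead(self.backbone.out_channels, config.head_hidden)

    def forward(self, rgb: Tensor, depth: Tensor) -> Tensor:
        if self.modality == "rgb":
            x = rgb
        else:
            x = nn.concat([depth, depth, depth], axis=1)
        return self.head(self.backbone(x))


class EarlyFusionNet(nn.Module):
    """Input-level fusion: RGB + depth stacked into a 4-channel image."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.backbone = _Backbone(config, 4)
        self.head = RegressionHead(self.backbone.out_channels, config.head_hidden)

    def forward(self, rgb: Tensor, depth: Tensor) -> Tensor:
        return self.head(self.backbone(nn.concat([rgb, depth], axis=1)))


class LateFusionNet(nn.Module):
    """Feature-level fusion: independent backbones, concatenated features."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.backbone_r = _Backbone(config, 3)
        self.backbone_d = _Backbone(config, 3)
        self.proj = nn.Conv2d(2 * self.backbone_r.out_channels,
                              self.backbone_r.out_channels, 1)
        self.head = RegressionHead(self.backbone_r.out_channels,
                                   config.head_hidden)

    def forward(self, rgb: Tensor, depth: Tensor) -> Tensor:
        fr = self.backbone_r(rgb)
        fd = self.backbone_d(nn.concat([depth, depth, depth], axis=1))
        return self.head(self.proj(nn.concat([fr, fd], axis=1)))


def build_model(config: ModelConfig, modality: str = "rgbd",
                topology: str = "multiscale") -> nn.Module:
    """Instantiate a model variant.

    modality: 'rgbd' (default) or a single modality baseline;
    topology (rgbd only): 'multiscale' (the full network), 'early', 'late'.
    """
    if modality in ("rgb", "depth"):
        return SingleStreamNet(config, modality)
    if modality != "rgbd":
        raise ValueError(f"unknown modality {modality!r}")
    if topology == "multiscale":
        return WeightNet(config)
    if topology == "early":
        return EarlyFusionNet(config)
    if topology == "late":
        return LateFusionNet(config)
    raise ValueError(f"unknown topology {topology!r}")
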