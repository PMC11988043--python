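"""Two-branch encoder with bidirectional cross-modality supplementation.

One backbone stage stack per modality, six stages each.  In stages 1-4 a
Cross-Modality Feature Supplementation (CFS) block fuses the two branches'
stage outputs and injects the fused feature back into each branch through a
sigmoid attention gate:

    fF  = FF(fR, fD)
    bfR = fR + sigmoid(BAM(fR)) * fF
    bfD = fD + sigmoid(BAM(fD)) * fF

and the supplemented features feed the next stage.  Stages 5-6 process both
branches with a single shared stack: high-level features of the two
modalities are similar enough that sharing halves that part of the
parameter budget.

The FF (feature fusion) block smooths both inputs with 1x1 convolutions,
highlights shared content with an element-wise product, and merges the
residual-enhanced pair with a depthwise-separable 3x3 convolution:

    fF = DSConv3x3([ fbar_F + fbar_a , fbar_F + fbar_b ]),
    fbar_F = fbar_a * fbar_b,  fbar_a = Conv1x1(fa),  fbar_b = Conv1x1(fb).

BAM (bottleneck attention) sums a channel path (global average pool ->
bottleneck MLP) and a spatial path (1x1 reduce -> two dilated 3x3 -> 1x1 to
one channel), broadcast to the input shape; it returns pre-sigmoid logits.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Tensor

__all__ = ["FeatureFusion", "BAM", "CFS", "BackboneStage", "TwoStreamEncoder"]


class FeatureFusion(nn.Module):
    """FF block; output has `out_channels` at the inputs' spatial size."""

    def __init__(self, in_channels_a: int, in_channels_b: int, out_channels: int):
        super().__init__()
        self.smooth_a = nn.Conv2d(in_channels_a, out_channels, 1)
        self.smooth_b = nn.Conv2d(in_channels_b, out_channels, 1)
        self.merge = nn.DepthwiseSeparableConv2d(2 * out_channels, out_channels)

    def forward(self, fa: Tensor, fb: Tensor) -> Tensor:
        if fa.shape[2:] != fb.shape[2:]:
            raise ValueError(f"spatial mismatch {fa.shape[2:]} vs {fb.shape[2:]}")
        sa = self.smooth_a(fa)
        sb = self.smooth_b(fb)
        shared = sa * sb
        return self.merge(nn.concat([shared + sa, shared + sb], axis=1))


class BAM(nn.Module):
    """Bottleneck attention: channel + spatial paths, summed logits."""

    def __init__(self, channels: int, reduction: int = 16, dilation: int = 4):
        super().__init__()
        if channels < reduction:
            raise ValueError(
                f"channels ({channels}) must be >= reduction ({reduction})")
        mid = channels // reduction
        self.fc1 = nn.Linear(channels, mid)
        self.fc2 = nn.Linear(mid, channels)
        self.sp_reduce = nn.Conv2d(channels, mid, 1)
        self.sp_conv1 = nn.Conv2d(mid, mid, 3, padding=dilation, dilation=dilation)
        self.sp_conv2 = nn.Conv2d(mid, mid, 3, padding=dilation, dilation=dilation)
        self.sp_out = nn.Conv2d(mid, 1, 1)

    @staticmethod
    def _leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
        return x.relu() - slope * (-x).relu()

    def forward(self, f: Tensor) -> Tensor:
        # leaky bottleneck: the pooled inputs are one-sided (post-ReLU
        # means), where a plain-ReLU bottleneck can die for every batch
        n, c = f.shape[0], f.shape[1]
        hidden = self._leaky_relu(self.fc1(nn.global_avg_pool(f)))
        ch = self.fc2(hidden).reshape(n, c, 1, 1)
        sp = self.sp_out(self.sp_conv2(self.sp_conv1(
            self.sp_reduce(f).relu()).relu()).relu())
        return ch + sp


class CFS(nn.Module):
    """Cross-modality feature supplementation for one encoder stage."""

    def __init__(self, channels: int, ff_channels: int | None = None,
                 bam_reduction: int = 16, bam_dilation: int = 4):
        super().__init__()
        ff_channels = channels if ff_channels is None else ff_channels
        if ff_channels != channels:
            raise ValueError("fused feature must match branch channels to "
                             "broadcast onto fR/fD")
        self.ff = FeatureFusion(channels, channels, ff_channels)
        self.bam_r = BAM(channels, bam_reduction, bam_dilation)
        self.bam_d = BAM(channels, bam_reduction, bam_dilation)

    def forward(self, fR: Tensor, fD: Tensor) -> tuple[Tensor, Tensor]:
        if fR.shape != fD.shape:
            raise ValueError(f"branch shapes differ: {fR.shape} vs {fD.shape}")
        fF = self.ff(fR, fD)
        bfR = fR + self.bam_r(fR).sigmoid() * fF
        bfD = fD + self.bam_d(fD).sigmoid() * fF
        return bfR, bfD


class BackboneStage(nn.Module):
    """One backbone stage: strided 3x3 conv then a depthwise-separable
    refinement, each followed by batch norm and ReLU (MobileNet-style)."""

    def __init__(self, in_channels: int, out_channels: int, stride: int):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, stride=stride,
                              padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.dw = nn.DepthwiseSeparableConv2d(out_channels, out_channels, bias=False)
        self.bn2 = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv(x)).relu()
        return self.bn2(self.dw(x)).relu()


class TwoStreamEncoder(nn.Module):
    """Six-stage RGB and depth branches with CFS in the configured stages.

    ``forward`` returns one six-level feature pyramid per branch: the
    supplemented features for stages with CFS, plain stage outputs
    elsewhere.  The supplemented features are what feeds the next stage.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        ch = config.stage_channels
        ff_ch = config.ff_channels or ch
        ins = (3,) + ch[:-1]
        self.stages_r = nn.ModuleList(
            BackboneStage(ins[i], ch[i], config.stage_strides[i]) for i in range(6))
        stages_d = []
        for i in range(6):
            if config.share_high_stages and i >= 4:
                stages_d.append(self.stages_r[i])     # same module object
            else:
                stages_d.append(BackboneStage(ins[i], ch[i], config.stage_strides[i]))
        self.stages_d = nn.ModuleList(stages_d)
        self.cfs = nn.ModuleList()
        self._cfs_by_stage: dict[int, CFS] = {}
        for stage in sorted(config.cfs_stages):
            block = CFS(ch[stage - 1], ff_ch[stage - 1],
                        config.bam_reduction, config.bam_dilation)
            self.cfs.append(block)
            self._cfs_by_stage[stage] = block
        if config.depth_input_mode == "learned1to3":
            self.depth_adapter = nn.Conv2d(1, 3, 1)
        else:
            self.depth_adapter = None

    def adapt_depth(self, depth: Tensor) -> Tensor:
        if self.depth_adapter is not None:
            return self.depth_adapter(depth)
        return nn.concat([depth, depth, depth], axis=1)

    def forward(self, rgb: Tensor, depth: Tensor
                ) -> tuple[list[Tensor], list[Tensor]]:
        if rgb.shape[2:] != depth.shape[2:]:
            raise ValueError("rgb and depth must share spatial size")
        xr, xd = rgb, self.adapt_depth(depth)
        pyr_r: list[Tensor] = []
        pyr_d: list[Tensor] = []
        for i in range(6):
            fr = self.stages_r[i](xr)
            fd = self.stages_d[i](xd)
            block = self._cfs_by_stage.get(i + 1)
            if block is not None:
                fr, fd = block(fr, fd)
            pyr_r.append(fr)
            pyr_d.append(fd)
            xr, xd = fr, fd
        return pyr_r, pyr_d
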