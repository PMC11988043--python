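"""Multi-scale cross-modality aggregation decoder.

Three Cross-Modality Feature Fusion (CFF) blocks tile the six encoder
stages coarse-to-fine: CFF-high fuses stages 5-6, CFF-middle stages 3-4,
CFF-low stages 1-2.  Within one CFF at level m the adjacent-scale features
of each branch are fused first, then the branches are fused across
modalities:

    bfRm = FF(bfR_lo, bfR_hi)
    bfDm = FF(bfD_lo, bfD_hi)
    fFm  = FF(bfRm, bfDm)

with the coarser input bilinearly upsampled beforehand.  Below the top
level, the previous (coarser) CFF output is upsampled and channel-
concatenated with fFm.  The result passes through a Receptive Field Block
(RFB): channels split in half, one half kept through a 1x1 convolution as a
residual, the other sent through parallel dilated 3x3 branches; both are
concatenated and channel-shuffled.

The cross-modality step (fFm) can be swapped for element-wise addition,
maximum, or concatenation+1x1 — the fusion-scheme ablation axis.
"""

from __future__ import annotations

from . import nn
from .config import ModelConfig
from .encoder import FeatureFusion
from .nn import Tensor

__all__ = ["RFB", "CFF", "Decoder"]


class RFB(nn.Module):
    """Receptive field block with channel split, dilated branches, shuffle."""

    def __init__(self, channels: int, dilations: tuple[int, ...] = (1, 3, 5)):
        super().__init__()
        if channels % 2:
            raise ValueError(f"RFB needs an even channel count, got {channels}")
        half = channels // 2
        self.residual = nn.Conv2d(half, half, 1)
        self.branches = nn.ModuleList(
            nn.Conv2d(half, half, 3, padding=d, dilation=d) for d in dilations)
        self.half = half

    def forward(self, f: Tensor) -> Tensor:
        a = f[:, :self.half]
        b = f[:, self.half:]
        a = self.residual(a)
        merged = self.branches[0](b)
        for branch in list(self.branches)[1:]:
            merged = merged + branch(b)
        merged = merged.relu()
        return nn.channel_shuffle(nn.concat([a, merged], axis=1), 2)


def _fuse_factory(scheme: str, width: int):
    """Cross-modality fusion step of a CFF block (the ablation axis)."""
    if scheme == "cff":
        return FeatureFusion(width, width, width)
    if scheme == "concatenation":
        class _Cat(nn.Module):
            def __init__(self):
                super().__init__()
                self.proj = nn.Conv2d(2 * width, width, 1)

            def forward(self, a, b):
                return self.proj(nn.concat([a, b], axis=1))
        return _Cat()
    if scheme == "addition":
        class _Add(nn.Module):
            def forward(self, a, b):
                return a + b
        return _Add()
    if scheme == "max":
        class _Max(nn.Module):
            def forward(self, a, b):
                return nn.maximum(a, b)
        return _Max()
    raise ValueError(f"unknown fusion scheme {scheme!r}")


class CFF(nn.Module):
    """One decoder level; output is at the finer ('lo') input's scale.

    Channel counts: every input is adapted to ``width`` by a 1x1
    convolution; with a previous-level feature the pre-RFB concatenation
    doubles that, so the output has ``2 * width`` channels, else ``width``.
    """

    @staticmethod
    def _adapter(in_ch: int, width: int) -> nn.Module:
        # normalising adapters keep the unnormalised FF/RFB cascade from
        # amplifying activations level over level
        return nn.Sequential(nn.Conv2d(in_ch, width, 1, bias=False),
                             nn.BatchNorm2d(width), nn.ReLU())

    def __init__(self, ch_r_lo: int, ch_r_hi: int, ch_d_lo: int, ch_d_hi: int,
                 width: int, rfb_dilations: tuple[int, ...] = (1, 3, 5),
                 prev_channels: int | None = None, fusion_scheme: str = "cff"):
        super().__init__()
        self.adapt_r_lo = self._adapter(ch_r_lo, width)
        self.adapt_r_hi = self._adapter(ch_r_hi, width)
        self.adapt_d_lo = self._adapter(ch_d_lo, width)
        self.adapt_d_hi = self._adapter(ch_d_hi, width)
        self.ff_r = FeatureFusion(width, width, width)
        self.ff_d = FeatureFusion(width, width, width)
        self.fuse = _fuse_factory(fusion_scheme, width)
        if prev_channels is not None:
            self.adapt_prev = self._adapter(prev_channels, width)
            rfb_channels = 2 * width
        else:
            self.adapt_prev = None
            rfb_channels = width
        self.rfb = RFB(rfb_channels, rfb_dilations)
        self.out_channels = rfb_channels

    def forward(self, bfR_lo: Tensor, bfR_hi: Tensor, bfD_lo: Tensor,
                bfD_hi: Tensor, f_prev: Tensor | None = None) -> Tensor:
        if (f_prev is None) != (self.adapt_prev is None):
            raise ValueError("f_prev presence must match construction")
        size = bfR_lo.shape[2:]
        r_lo = self.adapt_r_lo(bfR_lo)
        r_hi = nn.upsample_bilinear(self.adapt_r_hi(bfR_hi), size)
        d_lo = self.adapt_d_lo(bfD_lo)
        d_hi = nn.upsample_bilinear(self.adapt_d_hi(bfD_hi), size)
        bfRm = self.ff_r(r_lo, r_hi)
        bfDm = self.ff_d(d_lo, d_hi)
        fFm = self.fuse(bfRm, bfDm)
        if f_prev is not None:
            prev = nn.upsample_bilinear(self.adapt_prev(f_prev), size)
            fFm = nn.concat([fFm, prev], axis=1)
        return self.rfb(fFm)


class Decoder(nn.Module):
    """High -> middle -> low CFF cascade over the two feature pyramids."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        ch = config.stage_channels
        w = config.decoder_width
        dil = config.rfb_dilations
        scheme = config.fusion_scheme
        self.cff_high = CFF(ch[4], ch[5], ch[4], ch[5], w, dil,
                            prev_channels=None, fusion_scheme=scheme)
        self.cff_middle = CFF(ch[2], ch[3], ch[2], ch[3], w, dil,
                              prev_channels=self.cff_high.out_channels,
                              fusion_scheme=scheme)
        self.cff_low = CFF(ch[0], ch[1], ch[0], ch[1], w, dil,
                           prev_channels=self.cff_middle.out_channels,
                           fusion_scheme=scheme)
        self.out_channels = self.cff_low.out_channels

    def forward(self, pyramid_r: list[Tensor], pyramid_d: list[Tensor]) -> Tensor:
        if len(pyramid_r) != 6 or len(pyramid_d) != 6:
            raise ValueError("expected six features per branch")
        f_high = self.cff_high(pyramid_r[4], pyramid_r[5],
                               pyramid_d[4], pyramid_d[5])
        f_mid = self.cff_middle(pyramid_r[2], pyramid_r[3],
                                pyramid_d[2], pyramid_d[3], f_high)
        return self.cff_low(pyramid_r[0], pyramid_r[1],
                            pyramid_d[0], pyramid_d[1], f_mid)
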