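"""Decoder blocks: receptive-field refinement, cross-modality feature
fusion levels, and the coarse-to-fine cascade."""

import numpy as np
import pytest

from rgbdweight import nn
from rgbdweight.config import ModelConfig
from rgbdweight.decoder import CFF, Decoder, RFB
from rgbdweight.encoder import TwoStreamEncoder
from rgbdweight.nn import Tensor, channel_shuffle, upsample_bilinear

from reference import shuffle_permutation


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


# ----------------------------------------------------------------------- RFB
def test_rfb_preserves_shape_and_rejects_odd_channels(rng):
    rfb = RFB(32, dilations=(1, 3, 5))
    out = rfb(Tensor(rng.normal(size=(2, 32, 14, 14))))
    assert out.shape == (2, 32, 14, 14)
    with pytest.raises(ValueError, match="even"):
        RFB(7)


def test_rfb_zeroed_branches_give_permuted_residual(rng):
    """Identity 1x1 on the kept half + zeroed dilated half -> the output is
    exactly the channel-shuffled [A, 0]."""
    rfb = RFB(8, dilations=(1, 2))
    _zero_params(rfb)
    rfb.residual.weight.data[...] = np.eye(4)[:, :, None, None]
    x = rng.normal(size=(1, 8, 5, 5))
    out = rfb(Tensor(x))
    perm = shuffle_permutation(8, 2)
    expected = np.concatenate([x[:, :4], np.zeros((1, 4, 5, 5))], axis=1)[:, perm]
    assert np.array_equal(out.data, expected)


def test_channel_shuffle_matches_closed_form_interleaving():
    c = 8
    labelled = np.arange(c, dtype=float).reshape(1, c, 1, 1) * np.ones((1, c, 3, 3))
    out = channel_shuffle(Tensor(labelled), 2)
    perm = shuffle_permutation(c, 2)
    assert np.array_equal(out.data[0, :, 0, 0], np.array(perm, dtype=float))


def test_channel_shuffle_is_a_bijection(rng):
    x = rng.normal(size=(1, 12, 2, 2))
    out = channel_shuffle(Tensor(x), 3)
    assert sorted(out.data.ravel().tolist()) == sorted(x.ravel().tolist())


# ----------------------------------------------------------------------- CFF
def test_cff_zero_parameters_propagate_zero():
    cff = CFF(4, 6, 4, 6, width=8, prev_channels=None)
    _zero_params(cff)
    out = cff(Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 6, 4, 4))),
              Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 6, 4, 4))))
    assert np.array_equal(out.data, np.zeros_like(out.data))


def test_cff_prev_feature_doubles_pre_rfb_channels():
    no_prev = CFF(4, 6, 4, 6, width=8, prev_channels=None)
    with_prev = CFF(4, 6, 4, 6, width=8, prev_channels=10)
    assert no_prev.rfb.half * 2 == 8
    assert with_prev.rfb.half * 2 == 16
    assert with_prev.out_channels - no_prev.out_channels == 8
    with pytest.raises(ValueError, match="f_prev"):
        no_prev(Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 6, 4, 4))),
                Tensor(np.zeros((1, 4, 8, 8))), Tensor(np.zeros((1, 6, 4, 4))),
                Tensor(np.zeros((1, 10, 2, 2))))


def test_cff_equals_composition_of_verified_blocks(rng):
    """The module must equal the manual composition of its own adapter,
    fusion, upsampling, concatenation and refinement steps."""
    nn.seed_init(11)
    cff = CFF(4, 6, 4, 6, width=8, prev_channels=10)
    cff.eval()
    r_lo = Tensor(rng.normal(size=(1, 4, 8, 8)))
    r_hi = Tensor(rng.normal(size=(1, 6, 4, 4)))
    d_lo = Tensor(rng.normal(size=(1, 4, 8, 8)))
    d_hi = Tensor(rng.normal(size=(1, 6, 4, 4)))
    prev = Tensor(rng.normal(size=(1, 10, 2, 2)))
    out = cff(r_lo, r_hi, d_lo, d_hi, prev)

    bfRm = cff.ff_r(cff.adapt_r_lo(r_lo),
                    upsample_bilinear(cff.adapt_r_hi(r_hi), (8, 8)))
    bfDm = cff.ff_d(cff.adapt_d_lo(d_lo),
                    upsample_bilinear(cff.adapt_d_hi(d_hi), (8, 8)))
    fFm = cff.fuse(bfRm, bfDm)
    cat = nn.concat([fFm, upsample_bilinear(cff.adapt_prev(prev), (8, 8))], axis=1)
    manual = cff.rfb(cat)
    assert np.abs(out.data - manual.data).max() < 1e-6


@pytest.mark.parametrize("scheme", ["addition", "max", "concatenation"])
def test_cff_alternative_fusion_schemes_run(rng, scheme):
    cff = CFF(4, 4, 4, 4, width=6, fusion_scheme=scheme)
    out = cff(Tensor(rng.normal(size=(1, 4, 8, 8))),
              Tensor(rng.normal(size=(1, 4, 4, 4))),
              Tensor(rng.normal(size=(1, 4, 8, 8))),
              Tensor(rng.normal(size=(1, 4, 4, 4))))
    assert out.shape == (1, 6, 8, 8)


# -------------------------------------------------------------------- decode
def test_decode_output_at_finest_pyramid_scale(rng, tiny_config):
    enc = TwoStreamEncoder(tiny_config)
    dec = Decoder(tiny_config)
    enc.eval(), dec.eval()
    pyr_r, pyr_d = enc(Tensor(rng.normal(size=(1, 3, 32, 32))),
                       Tensor(rng.normal(size=(1, 1, 32, 32))))
    out = dec(pyr_r, pyr_d)
    assert out.shape == (1, dec.out_channels, pyr_r[0].shape[2], pyr_r[0].shape[3])
    with pytest.raises(ValueError, match="six"):
        dec(pyr_r[:5], pyr_d[:5])


def test_decode_zero_everything_gives_zero(tiny_config):
    dec = Decoder(tiny_config)
    _zero_params(dec)
    ch = tiny_config.stage_channels
    sizes = [16, 8, 4, 2, 1, 1]
    pyr = [Tensor(np.zeros((1, ch[i], sizes[i], sizes[i]))) for i in range(6)]
    out = dec(pyr, pyr)
    assert np.array_equal(out.data, np.zeros_like(out.data))


def test_decode_reruns_are_identical(rng, tiny_config):
    nn.seed_init(21)
    enc, dec = TwoStreamEncoder(tiny_config), Decoder(tiny_config)
    enc.eval(), dec.eval()
    rgb = rng.normal(size=(1, 3, 32, 32))
    depth = rng.normal(size=(1, 1, 32, 32))
    outs = []
    for _ in range(2):
        pyr_r, pyr_d = enc(Tensor(rgb), Tensor(depth))
        outs.append(dec(pyr_r, pyr_d).data)
    assert np.abs(outs[0] - outs[1]).max() < 1e-6
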