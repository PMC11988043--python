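"""Encoder blocks: feature fusion, bottleneck attention, cross-modality
supplementation, and the two-branch six-stage backbone contracts."""

import numpy as np
import pytest

from rgbdweight import nn
from rgbdweight.config import ModelConfig
from rgbdweight.encoder import BAM, CFS, FeatureFusion, TwoStreamEncoder
from rgbdweight.nn import Tensor

from reference import bam_ref, cfs_ref, ff_ref


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


def _seed_params(module, rng, scale=0.3):
    for p in module.parameters():
        p.data[...] = rng.normal(0.0, scale, p.shape)


# ------------------------------------------------------------------------ FF
def test_ff_zero_parameters_propagate_zero(rng):
    ff = FeatureFusion(2, 2, 2)
    _zero_params(ff)
    out = ff(Tensor(np.zeros((1, 2, 4, 4))), Tensor(rng.normal(size=(1, 2, 4, 4))))
    assert np.array_equal(out.data, np.zeros((1, 2, 4, 4)))


def test_ff_shape_contract(rng):
    ff = FeatureFusion(8, 8, 5)
    out = ff(Tensor(rng.normal(size=(2, 8, 16, 16))),
             Tensor(rng.normal(size=(2, 8, 16, 16))))
    assert out.shape == (2, 5, 16, 16)
    with pytest.raises(ValueError, match="spatial"):
        ff(Tensor(np.zeros((1, 8, 8, 8))), Tensor(np.zeros((1, 8, 4, 4))))


def test_ff_matches_hand_computed_fusion_formula(rng):
    """smooth -> multiply -> residual concat -> depthwise-separable merge,
    recomputed with naive loops on a 1-channel 2x2 fixture."""
    ff = FeatureFusion(1, 1, 1)
    _seed_params(ff, rng)
    fa = rng.normal(size=(1, 2, 2))
    fb = rng.normal(size=(1, 2, 2))
    out = ff(Tensor(fa[None]), Tensor(fb[None]))
    assert np.allclose(out.data[0], ff_ref(ff, fa, fb), atol=1e-9)


# ----------------------------------------------------------------------- BAM
def test_bam_constant_input_zeroed_heads_give_half_gate():
    bam = BAM(4, reduction=2, dilation=1)
    _zero_params(bam.fc2)
    _zero_params(bam.sp_out)
    out = bam(Tensor(np.full((1, 4, 5, 5), 3.0)))
    assert np.array_equal(out.data, np.zeros((1, 4, 5, 5)))
    assert np.allclose(out.sigmoid().data, 0.5)


def test_bam_shape_and_validation(rng):
    out = BAM(16, reduction=16, dilation=4)(Tensor(rng.normal(size=(2, 16, 8, 8))))
    assert out.shape == (2, 16, 8, 8)
    with pytest.raises(ValueError, match="reduction"):
        BAM(8, reduction=16)


def test_bam_matches_hand_computed_channel_plus_spatial_sum(rng):
    bam = BAM(2, reduction=2, dilation=1)
    _seed_params(bam, rng)
    f = rng.normal(size=(2, 3, 3))
    out = bam(Tensor(f[None]))
    assert np.allclose(out.data[0], bam_ref(bam, f), atol=1e-9)


# ----------------------------------------------------------------------- CFS
def test_cfs_zero_fusion_is_exact_identity(rng):
    """With the fused feature forced to zero the supplementation reduces to
    the identity on both branches, bit for bit."""
    cfs = CFS(4, bam_reduction=2, bam_dilation=2)
    _zero_params(cfs.ff.merge.pointwise)
    fR = Tensor(rng.normal(size=(2, 4, 8, 8)))
    fD = Tensor(rng.normal(size=(2, 4, 8, 8)))
    bfR, bfD = cfs(fR, fD)
    assert np.array_equal(bfR.data, fR.data)
    assert np.array_equal(bfD.data, fD.data)


def test_cfs_saturated_gate_adds_full_fused_feature(rng):
    cfs = CFS(4, bam_reduction=2, bam_dilation=2)
    for bam in (cfs.bam_r, cfs.bam_d):
        object.__setattr__(bam, "forward",
                           lambda f: Tensor(np.full(f.shape, 1e3)))
    fR = Tensor(rng.normal(size=(1, 4, 6, 6)))
    fD = Tensor(rng.normal(size=(1, 4, 6, 6)))
    fF = cfs.ff(fR, fD)
    bfR, bfD = cfs(fR, fD)
    assert np.array_equal(bfR.data, fR.data + fF.data)
    assert np.array_equal(bfD.data, fD.data + fF.data)


def test_cfs_matches_independent_recomputation(rng):
    cfs = CFS(4, bam_reduction=2, bam_dilation=1)
    _seed_params(cfs, rng)
    fR = rng.normal(size=(4, 8, 8))
    fD = rng.normal(size=(4, 8, 8))
    bfR, bfD = cfs(Tensor(fR[None]), Tensor(fD[None]))
    rR, rD = cfs_ref(cfs, fR, fD)
    assert np.abs(bfR.data[0] - rR).max() < 1e-6
    assert np.abs(bfD.data[0] - rD).max() < 1e-6


def test_cfs_gate_boundedness(rng):
    """sigmoid-gated supplementation can never move a branch further than
    the fused feature's own magnitude."""
    cfs = CFS(4, bam_reduction=2, bam_dilation=2)
    _seed_params(cfs, rng, scale=0.8)
    fR = Tensor(rng.normal(size=(2, 4, 8, 8)))
    fD = Tensor(rng.normal(size=(2, 4, 8, 8)))
    fF = cfs.ff(fR, fD)
    bfR, bfD = cfs(fR, fD)
    bound = np.abs(fF.data).max()
    assert np.abs(bfR.data - fR.data).max() <= bound + 1e-12
    assert np.abs(bfD.data - fD.data).max() <= bound + 1e-12


# -------------------------------------------------------------------- encode
def test_encoder_pyramid_shapes_non_increasing(rng, tiny_config):
    enc = TwoStreamEncoder(tiny_config)
    pyr_r, pyr_d = enc(Tensor(rng.normal(size=(1, 3, 32, 32))),
                       Tensor(rng.normal(size=(1, 1, 32, 32))))
    assert len(pyr_r) == len(pyr_d) == 6
    sizes = [f.shape[2] for f in pyr_r]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
    for i, (fr, fd) in enumerate(zip(pyr_r, pyr_d)):
        assert fr.shape == fd.shape
        assert fr.shape[1] == tiny_config.stage_channels[i]


def test_encoder_without_cfs_equals_independent_branch_runs(rng, tiny_config):
    cfg = tiny_config.replace(cfs_stages=())
    nn.seed_init(5)
    enc = TwoStreamEncoder(cfg)
    rgb = Tensor(rng.normal(size=(1, 3, 32, 32)))
    depth = Tensor(rng.normal(size=(1, 1, 32, 32)))
    enc.eval()
    pyr_r, pyr_d = enc(rgb, depth)
    # manual independent stage runs
    x = rgb
    for i in range(6):
        x = enc.stages_r[i](x)
        assert np.array_equal(x.data, pyr_r[i].data)
    x = enc.adapt_depth(depth)
    for i in range(6):
        x = enc.stages_d[i](x)
        assert np.array_equal(x.data, pyr_d[i].data)


def test_shared_high_stages_share_parameter_objects(tiny_config):
    shared = TwoStreamEncoder(tiny_config)
    unshared = TwoStreamEncoder(tiny_config.replace(share_high_stages=False))
    assert shared.stages_r[4] is shared.stages_d[4]
    assert shared.stages_r[5] is shared.stages_d[5]
    high_copy = sum(p.size for p in shared.stages_r[4].parameters()) \
        + sum(p.size for p in shared.stages_r[5].parameters())
    assert unshared.num_parameters() - shared.num_parameters() == high_copy


def test_learned_depth_adapter_mode(rng, tiny_config):
    enc = TwoStreamEncoder(tiny_config.replace(depth_input_mode="learned1to3"))
    depth = Tensor(rng.normal(size=(2, 1, 16, 16)))
    out = enc.adapt_depth(depth)
    assert out.shape == (2, 3, 16, 16)
    replicate = TwoStreamEncoder(tiny_config).adapt_depth(depth)
    assert np.array_equal(replicate.data[:, 0], depth.data[:, 0])
    assert np.array_equal(replicate.data[:, 1], depth.data[:, 0])
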