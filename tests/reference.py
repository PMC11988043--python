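"""Independent plain-numpy reference implementations of the network's
building blocks, written as direct loop/array transcriptions of the
defining formulas.  They share no code with the package's autodiff path and
serve as oracles in the unit and acceptance tests."""

import numpy as np


def conv2d_ref(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """Naive convolution. x: (C,H,W); w: (Cout,Cin/groups,kh,kw)."""
    C, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    OH = (H + 2 * padding - (kh - 1) * dilation - 1) // stride + 1
    OW = (W + 2 * padding - (kw - 1) * dilation - 1) // stride + 1
    out = np.zeros((Cout, OH, OW))
    cg, og = C // groups, Cout // groups
    for o in range(Cout):
        g = o // og
        for oh in range(OH):
            for ow in range(OW):
                acc = 0.0
                for ci in range(Cin_g):
                    c = g * cg + ci
                    for i in range(kh):
                        for j in range(kw):
                            acc += (xp[c, oh * stride + i * dilation,
                                       ow * stride + j * dilation]
                                    * w[o, ci, i, j])
                out[o, oh, ow] = acc
        if b is not None:
            out[o] += b[o]
    return out


def sigmoid_ref(x):
    return 1.0 / (1.0 + np.exp(-x))


def ff_ref(module, fa, fb):
    """Feature fusion: 1x1 smoothing, element-wise product, residual
    concatenation, depthwise-separable 3x3 merge."""
    sa = conv2d_ref(fa, module.smooth_a.weight.data, module.smooth_a.bias.data)
    sb = conv2d_ref(fb, module.smooth_b.weight.data, module.smooth_b.bias.data)
    shared = sa * sb
    cat = np.concatenate([shared + sa, shared + sb], axis=0)
    dw = conv2d_ref(cat, module.merge.depthwise.weight.data, None,
                    padding=1, groups=cat.shape[0])
    return conv2d_ref(dw, module.merge.pointwise.weight.data,
                      module.merge.pointwise.bias.data)


def bam_ref(module, f):
    """Bottleneck attention logits: channel MLP path + dilated spatial path."""
    C = f.shape[0]
    gap = f.mean(axis=(1, 2))
    pre = gap @ module.fc1.weight.data + module.fc1.bias.data
    h = np.where(pre > 0, pre, 0.01 * pre)
    ch = (h @ module.fc2.weight.data + module.fc2.bias.data).reshape(C, 1, 1)
    d = module.sp_conv1.dilation
    s = np.maximum(conv2d_ref(f, module.sp_reduce.weight.data,
                              module.sp_reduce.bias.data), 0.0)
    s = np.maximum(conv2d_ref(s, module.sp_conv1.weight.data,
                              module.sp_conv1.bias.data,
                              padding=d, dilation=d), 0.0)
    s = np.maximum(conv2d_ref(s, module.sp_conv2.weight.data,
                              module.sp_conv2.bias.data,
                              padding=d, dilation=d), 0.0)
    sp = conv2d_ref(s, module.sp_out.weight.data, module.sp_out.bias.data)
    return ch + sp


def cfs_ref(module, fR, fD):
    """Cross-modality feature supplementation:
    bfM = fM + sigmoid(BAM(fM)) * FF(fR, fD)."""
    fF = ff_ref(module.ff, fR, fD)
    bfR = fR + sigmoid_ref(bam_ref(module.bam_r, fR)) * fF
    bfD = fD + sigmoid_ref(bam_ref(module.bam_d, fD)) * fF
    return bfR, bfD


def shuffle_permutation(channels, groups=2):
    """Closed-form channel-shuffle permutation: output k takes input
    (k % groups) * (channels // groups) + k // groups."""
    per = channels // groups
    return [(k % groups) * per + k // groups for k in range(channels)]
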