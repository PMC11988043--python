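"""Structured primitives: 2-D convolution and bilinear resampling.

``conv2d`` decomposes the kernel into its kh*kw taps and accumulates one
matrix product per tap over strided input slices — no im2col copy, every
flop goes through BLAS.  1x1 convolutions collapse to a single tensordot.
Grouped convolution covers the dense (``groups=1``) and depthwise
(``groups == in_channels``) cases the network uses, plus a generic loop.

``upsample_bilinear`` (align_corners=False) is expressed as a pair of 1-D
interpolation matrices applied to rows and columns, so its backward is just
the transposed matrices.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "upsample_bilinear", "global_avg_pool", "channel_shuffle"]


def _out_size(n: int, k: int, stride: int, pad: int, dil: int) -> int:
    ke = (k - 1) * dil + 1
    return (n + 2 * pad - ke) // stride + 1


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    xd = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    wk = w.data[:, :, 0, 0]                       # (Cout, Cin)
    out = np.tensordot(wk, xd, axes=(1, 1)).transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        dw = np.tensordot(g, xd, axes=([0, 2, 3], [0, 2, 3]))
        dxs = np.tensordot(wk.T, g, axes=(1, 1)).transpose(1, 0, 2, 3)
        if stride > 1:
            dx = np.zeros_like(x.data)
            dx[:, :, ::stride, ::stride] = dxs
        else:
            dx = dxs
        grads = [(x, dx), (w, dw[:, :, None, None])]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return x._make(out, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Cross-correlation of `x` (N,C,H,W) with `w` (Cout,Cin/groups,kh,kw)."""
    N, C, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    if C % groups or Cout % groups or Cin_g * groups != C:
        raise ValueError(
            f"incompatible channels: x has {C}, w expects {Cin_g}*{groups}")
    if kh == 1 and kw == 1 and padding == 0 and groups == 1:
        return _conv1x1(x, w, b, stride)

    # channel-first (C,N,H,W) internal layout keeps every tap GEMM and its
    # accumulation contiguous; transposed back once at the end
    pad = padding
    xt = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3))
    xp = np.pad(xt, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xt
    OH = _out_size(H, kh, stride, pad, dilation)
    OW = _out_size(W, kw, stride, pad, dilation)
    depthwise = groups == C and Cout == C and Cin_g == 1
    cg, og = C // groups, Cout // groups

    def tap(i, j):
        hi, wj = i * dilation, j * dilation
        return xp[:, :, hi:hi + stride * OH:stride, wj:wj + stride * OW:stride]

    out_t = np.zeros((Cout, N, OH, OW), dtype=xt.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = tap(i, j)
            if groups == 1:
                out_t += np.tensordot(w.data[:, :, i, j], sl, axes=(1, 0))
            elif depthwise:
                out_t += sl * w.data[:, 0, i, j].reshape(-1, 1, 1, 1)
            else:
                for g in range(groups):
                    out_t[g * og:(g + 1) * og] += np.tensordot(
                        w.data[g * og:(g + 1) * og, :, i, j],
                        sl[g * cg:(g + 1) * cg], axes=(1, 0))
    out = out_t.transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(gout):
        gt = np.ascontiguousarray(gout.transpose(1, 0, 2, 3))
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            hi = i * dilation
            for j in range(kw):
                wj = j * dilation
                sl = tap(i, j)
                dsl = dxp[:, :, hi:hi + stride * OH:stride,
                          wj:wj + stride * OW:stride]
                if groups == 1:
                    dw[:, :, i, j] = np.tensordot(
                        gt, sl, axes=([1, 2, 3], [1, 2, 3]))
                    dsl += np.tensordot(w.data[:, :, i, j].T, gt, axes=(1, 0))
                elif depthwise:
                    dw[:, 0, i, j] = (gt * sl).sum(axis=(1, 2, 3))
                    dsl += gt * w.data[:, 0, i, j].reshape(-1, 1, 1, 1)
                else:
                    for g in range(groups):
                        go = gt[g * og:(g + 1) * og]
                        dw[g * og:(g + 1) * og, :, i, j] = np.tensordot(
                            go, sl[g * cg:(g + 1) * cg],
                            axes=([1, 2, 3], [1, 2, 3]))
                        dsl[g * cg:(g + 1) * cg] += np.tensordot(
                            w.data[g * og:(g + 1) * og, :, i, j].T, go,
                            axes=(1, 0))
        dxt = dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp
        grads = [(x, dxt.transpose(1, 0, 2, 3)), (w, dw)]
        if b is not None:
            grads.append((b, gout.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return x._make(out, parents, backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (align_corners=False), (n_out, n_in)."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), hi] += frac
    return A


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize (N,C,H,W) feature maps to `size` with bilinear interpolation."""
    N, C, H, W = x.shape
    oh, ow = int(size[0]), int(size[1])
    if (oh, ow) == (H, W):
        return x
    A = _interp_matrix(oh, H).astype(x.data.dtype)   # rows
    B = _interp_matrix(ow, W).astype(x.data.dtype)   # cols
    out = np.einsum("ph,nchw,qw->ncpq", A, x.data, B, optimize=True)

    def backward(g):
        dx = np.einsum("ph,ncpq,qw->nchw", A, g, B, optimize=True)
        return ((x, dx),)

    return x._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    return x.mean(axis=(2, 3))


def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """Interleave channel groups: [g0c0, g1c0, g0c1, g1c1, ...]."""
    N, C, H, W = x.shape
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    return (x.reshape(N, groups, C // groups, H, W)
             .transpose((0, 2, 1, 3, 4))
             .reshape(N, C, H, W))
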