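"""Spatial primitives (conv2d, max-pool, nearest upsampling) for the
autodiff engine.

Convolution runs as an im2col view + ``tensordot`` (so the heavy lifting is
a single BLAS call); its backward scatters gradients with a small loop over
the ``kh * kw`` kernel offsets, which keeps everything vectorized without a
Python loop over pixels.  All tensors are NCHW.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def _patch_view(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, dh: int, dw: int):
    """Read-only sliding-window view (N, C, Ho, Wo, kh, kw) of padded input."""
    n, c, h, w = xp.shape
    ho = (h - (kh - 1) * dh - 1) // sh + 1
    wo = (w - (kw - 1) * dw - 1) // sw + 1
    sn, sc, sy, sx = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sy * sh, sx * sw, sy * dh, sx * dw),
        writeable=False,
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, NCHW, square stride/padding/dilation."""
    kh, kw = weight.shape[2], weight.shape[3]
    s, p, d = int(stride), int(padding), int(dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    view = _patch_view(xp, kh, kw, s, s, d, d)
    # (N,C,Ho,Wo,kh,kw) x (O,C,kh,kw) -> (N,Ho,Wo,O)
    out = np.tensordot(view, weight.data, axes=([1, 4, 5], [1, 2, 3]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1)
    n, _, ho, wo = out.shape
    macs = weight.data.size * ho * wo * n  # Cout*Cin*kh*kw * output area
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        if weight.requires_grad:
            gw = np.tensordot(g, view, axes=([0, 2, 3], [0, 2, 3]))  # (O,C,kh,kw)
            weight._accum(gw.astype(np.float32))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    # (N,O,Ho,Wo) x (O,C) -> (N,Ho,Wo,C)
                    gi = np.tensordot(g, weight.data[:, :, i, j], axes=([1], [0]))
                    gxp[:, :, i * d : i * d + ho * s : s, j * d : j * d + wo * s : s] += (
                        gi.transpose(0, 3, 1, 2)
                    )
            if p:
                gxp = gxp[:, :, p:-p, p:-p]
            x._accum(gxp)

    conv2d.last_macs = macs  # read back by the Conv2d module for FLOP accounting
    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, *, stride: int = 1, padding: int = 0) -> Tensor:
    """Max pooling (used with stride 1 + same padding in the SPPF pyramid)."""
    k, s, p = int(kernel), int(stride), int(padding)
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    else:
        xp = x.data
    view = _patch_view(xp, k, k, s, s, 1, 1)
    n, c, ho, wo = view.shape[:4]
    flat = view.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gxp = np.zeros_like(xp)
        for idx in range(k * k):
            mask = arg == idx
            if not mask.any():
                continue
            i, j = divmod(idx, k)
            gxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += g * mask
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        x._accum(gxp)

    return Tensor._make(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(data, (x,), bw)
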