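"""Differentiable building blocks: 3D (transposed) convolution, activations,
and the centred orthonormal FFT-magnitude representation used by the
frequency structure loss.

Convolution is implemented as im2col + matmul; its input gradient is the
standard col2im scatter-add.  The transposed convolution is restricted to
kernel == stride (non-overlapping upsampling), which is all the generator
needs and keeps both directions exact.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .autograd import Tensor, _make

__all__ = [
    "conv3d",
    "conv_transpose3d",
    "prelu",
    "leaky_relu",
    "frequency_representation_t",
]


def _triple(v):
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected length-3 tuple, got {v!r}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def _im2col(xp: np.ndarray, kernel, stride, out_shape):
    kd, kh, kw = kernel
    sd, sh, sw = stride
    do, ho, wo = out_shape
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::sd, ::sh, ::sw]  # (N, C, do, ho, wo, kd, kh, kw)
    n, c = xp.shape[:2]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do * ho * wo, c * kd * kh * kw)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, x_padded_shape, kernel, stride, out_shape):
    """Adjoint of ``_im2col``: scatter-add column gradients back to the padded input."""
    n, c = x_padded_shape[:2]
    kd, kh, kw = kernel
    sd, sh, sw = stride
    do, ho, wo = out_shape
    g = cols.reshape(n, do, ho, wo, c, kd, kh, kw).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    xg = np.zeros(x_padded_shape, dtype=cols.dtype)
    for i, j, k in product(range(kd), range(kh), range(kw)):
        xg[:, :, i : i + sd * do : sd, j : j + sh * ho : sh, k : k + sw * wo : sw] += g[..., i, j, k]
    return xg


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride=1, padding=0) -> Tensor:
    """3D convolution on (N, C, D, H, W) with per-axis stride and zero padding."""
    stride = _triple(stride)
    padding = _triple(padding)
    n, ci, d, h, w = x.shape
    co, ci_w, kd, kh, kw = weight.shape
    if ci != ci_w:
        raise ValueError(f"conv3d channel mismatch: input {ci}, weight {ci_w}")
    pd, ph, pw = padding
    sd, sh, sw = stride
    dp, hp, wp = d + 2 * pd, h + 2 * ph, w + 2 * pw
    if dp < kd or hp < kh or wp < kw:
        raise ValueError(
            f"conv3d input {(d, h, w)} (padded {(dp, hp, wp)}) smaller than kernel {(kd, kh, kw)}"
        )
    do = (dp - kd) // sd + 1
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1

    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    cols = _im2col(xp, (kd, kh, kw), stride, (do, ho, wo))
    w2 = weight.data.reshape(co, -1)
    out = cols @ w2.T  # (N, P, Co)
    out = out.transpose(0, 2, 1).reshape(n, co, do, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    res = _make(out, parents)
    if res.requires_grad:

        def backward(g):
            g2 = g.reshape(n, co, -1).transpose(0, 2, 1)  # (N, P, Co)
            grad_w = np.einsum("npo,npk->ok", g2, cols).reshape(weight.shape)
            grad_cols = g2 @ w2  # (N, P, Ci*k^3)
            gxp = _col2im(grad_cols, xp.shape, (kd, kh, kw), stride, (do, ho, wo))
            gx = gxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]
            if bias is None:
                return gx, grad_w
            grad_b = g.sum(axis=(0, 2, 3, 4))
            return gx, grad_w, grad_b

        res._backward_fn = backward
    return res


def conv_transpose3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride=2) -> Tensor:
    """Transposed 3D convolution with kernel == stride (exact upsampling).

    ``weight`` has shape (C_in, C_out, kd, kh, kw) with (kd, kh, kw) == stride.
    """
    stride = _triple(stride)
    n, ci, d, h, w = x.shape
    ci_w, co, kd, kh, kw = weight.shape
    if ci != ci_w:
        raise ValueError(f"conv_transpose3d channel mismatch: input {ci}, weight {ci_w}")
    if (kd, kh, kw) != stride:
        raise ValueError("conv_transpose3d requires kernel == stride")

    # tmp[n, d, h, w, o, i, j, k]
    tmp = np.tensordot(x.data, weight.data, axes=([1], [0]))
    out = np.zeros((n, co, d * kd, h * kh, w * kw), dtype=np.float64)
    for i, j, k in product(range(kd), range(kh), range(kw)):
        out[:, :, i::kd, j::kh, k::kw] = tmp[..., i, j, k].transpose(0, 4, 1, 2, 3)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    res = _make(out, parents)
    if res.requires_grad:

        def backward(g):
            gx = np.zeros_like(x.data)
            gw = np.zeros_like(weight.data)
            for i, j, k in product(range(kd), range(kh), range(kw)):
                gsub = g[:, :, i::kd, j::kh, k::kw]  # (N, Co, D, H, W)
                gx += np.einsum("nodhw,co->ncdhw", gsub, weight.data[:, :, i, j, k])
                gw[:, :, i, j, k] = np.einsum("ncdhw,nodhw->co", x.data, gsub)
            if bias is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3, 4))

        res._backward_fn = backward
    return res


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """PReLU with a per-channel learnable negative slope (alpha shape: (C,))."""
    c = x.shape[1]
    a = alpha.data.reshape(1, c, *([1] * (x.ndim - 2)))
    pos = x.data > 0
    out = np.where(pos, x.data, a * x.data)
    res = _make(out, (x, alpha))
    if res.requires_grad:

        def backward(g):
            gx = np.where(pos, g, a * g)
            axes = (0,) + tuple(range(2, x.ndim))
            ga = np.where(pos, 0.0, x.data * g).sum(axis=axes)
            return gx, ga

        res._backward_fn = backward
    return res


def leaky_relu(x: Tensor, negative_slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, negative_slope * x.data)
    res = _make(out, (x,))
    if res.requires_grad:
        res._backward_fn = lambda g: (np.where(pos, g, negative_slope * g),)
    return res


def frequency_representation_t(x: Tensor, convention: str = "ortho") -> Tensor:
    """Differentiable tanh-compressed centred DFT magnitude over the last 3 axes.

    Forward: rep = tanh(|fftshift(DFT(x))|) with the DFT scaled 1/sqrt(LMN)
    (``convention="ortho"``) or 1/(LMN) (``convention="forward"``).  The
    backward pass uses the adjoint DFT: for real input x and upstream
    gradient g, grad_x = Re(DFT_adj(ifftshift(g * (1 - rep^2) * F / |F|))).
    """
    if convention not in ("ortho", "forward"):
        raise ValueError(f"unknown DFT convention {convention!r}")
    axes = (-3, -2, -1)
    spec = np.fft.fftshift(np.fft.fftn(x.data, axes=axes, norm=convention), axes=axes)
    mag = np.abs(spec)
    rep = np.tanh(mag)
    res = _make(rep, (x,))
    if res.requires_grad:
        adj_norm = "ortho" if convention == "ortho" else "backward"

        def backward(g):
            dmag = g * (1.0 - rep * rep)
            direction = np.where(mag > 0, spec / np.maximum(mag, 1e-300), 0.0)
            gspec = dmag * direction
            gx = np.fft.ifftn(np.fft.ifftshift(gspec, axes=axes), axes=axes, norm=adj_norm).real
            return (gx,)

        res._backward_fn = backward
    return res
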