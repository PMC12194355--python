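"""Neural-network primitives (convolutions, normalization, pooling).

All primitives operate on NCHW :class:`~scintidenoise.nn.tensor.Tensor`
inputs and register hand-written vector-Jacobian products, so any network
composed from them is end-to-end differentiable. Convolutions use an
im2col/einsum formulation; their input gradient is scattered back with a
small loop over kernel offsets (kernels here are at most 5x5).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor, from_op


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weight (I = C_in/groups)."""
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    c_out, c_g, kh, kw = wd.shape
    if c != groups * c_g:
        raise ValueError(f"channel mismatch: input {c}, weight expects "
                         f"{groups * c_g} (groups={groups})")
    if c_out % groups:
        raise ValueError("out_channels must be divisible by groups")
    s, p = int(stride), int(padding)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"kernel {kh}x{kw} larger than padded input {hp}x{wp}")
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    depthwise = groups == c and c_g == 1
    if depthwise:
        y = np.einsum("nchwkl,ckl->nchw", win, wd[:, 0], optimize=True)
    elif groups == 1:
        y = np.einsum("nihwkl,oikl->nohw", win, wd, optimize=True)
    else:
        wing = win.reshape(n, groups, c_g, ho, wo, kh, kw)
        wg = wd.reshape(groups, c_out // groups, c_g, kh, kw)
        y = np.einsum("ngihwkl,goikl->ngohw", wing, wg,
                      optimize=True).reshape(n, c_out, ho, wo)
    y = np.ascontiguousarray(y)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)

    def vjp(g):
        gw = None
        if w.requires_grad or w._vjp is not None:
            if depthwise:
                gw = np.einsum("nchwkl,nchw->ckl", win, g,
                               optimize=True)[:, None]
            elif groups == 1:
                gw = np.einsum("nihwkl,nohw->oikl", win, g, optimize=True)
            else:
                wing = win.reshape(n, groups, c_g, ho, wo, kh, kw)
                gg = g.reshape(n, groups, c_out // groups, ho, wo)
                gw = np.einsum("ngihwkl,ngohw->goikl", wing, gg,
                               optimize=True).reshape(wd.shape)
        gx = None
        if x.requires_grad or x._vjp is not None:
            # one einsum for all kernel offsets, then strided scatter-add
            if depthwise:
                gcols = np.einsum("nchw,ckl->nchwkl", g, wd[:, 0],
                                  optimize=True)
            elif groups == 1:
                gcols = np.einsum("nohw,oikl->nihwkl", g, wd, optimize=True)
            else:
                gg = g.reshape(n, groups, c_out // groups, ho, wo)
                wg = wd.reshape(groups, c_out // groups, c_g, kh, kw)
                gcols = np.einsum("ngohw,goikl->ngihwkl", gg, wg,
                                  optimize=True).reshape(
                                      n, c, ho, wo, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + s * ho:s,
                        j:j + s * wo:s] += gcols[:, :, :, :, i, j]
            gx = gxp[:, :, p:p + h, p:p + wdt] if p else gxp
        if b is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return from_op(y, parents, vjp)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed 2-D convolution; weight layout (C_in, C_out, kh, kw).

    With kernel 4, stride 2, padding 1 this exactly doubles the spatial
    dimensions, and is the adjoint of :func:`conv2d` with shared weights.
    """
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    c_in, c_out, kh, kw = wd.shape
    if c != c_in:
        raise ValueError(f"channel mismatch: input {c}, weight expects {c_in}")
    s, p = int(stride), int(padding)
    hf = (h - 1) * s + kh
    wf = (wdt - 1) * s + kw
    yf = np.zeros((n, c_out, hf, wf), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            yf[:, :, i:i + s * h:s, j:j + s * wdt:s] += np.einsum(
                "nchw,co->nohw", xd, wd[:, :, i, j], optimize=True)
    y = yf[:, :, p:hf - p, p:wf - p] if p else yf
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)

    def vjp(g):
        gf = np.zeros((n, c_out, hf, wf), dtype=g.dtype)
        if p:
            gf[:, :, p:hf - p, p:wf - p] = g
        else:
            gf = g
        gx = None
        if x.requires_grad or x._vjp is not None:
            gx = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    gx += np.einsum(
                        "nohw,co->nchw",
                        gf[:, :, i:i + s * h:s, j:j + s * wdt:s],
                        wd[:, :, i, j], optimize=True)
        gw = None
        if w.requires_grad or w._vjp is not None:
            gw = np.empty_like(wd)
            for i in range(kh):
                for j in range(kw):
                    gw[:, :, i, j] = np.einsum(
                        "nchw,nohw->co", xd,
                        gf[:, :, i:i + s * h:s, j:j + s * wdt:s],
                        optimize=True)
        if b is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return from_op(y, parents, vjp)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, *,
               groups: int, eps: float = 1e-5) -> Tensor:
    """Group Normalization with per-channel affine terms."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    xg = x.reshape(n, groups, (c // groups) * h * w)
    mu = xg.mean(axis=2, keepdims=True)
    xc = xg - mu
    var = (xc * xc).mean(axis=2, keepdims=True)
    xn = xc / (var + eps).sqrt()
    y = xn.reshape(n, c, h, w)
    return y * gamma.reshape(1, c, 1, 1) + beta.reshape(1, c, 1, 1)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    y = x @ w
    return y if b is None else y + b


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC per-channel spatial mean (the GAP descriptor)."""
    return x.mean(axis=(2, 3))


def gaussian_kernel1d(sigma: float, radius: int) -> np.ndarray:
    """Sampled, normalized Gaussian tap weights (ndimage convention)."""
    xs = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 / sigma ** 2 * xs ** 2)
    return phi / phi.sum()


def separable_blur_valid(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Valid-mode separable blur of an (N,1,H,W) tensor by a 1-D kernel."""
    k = kernel.size
    kv = Tensor(kernel.reshape(1, 1, k, 1))
    kh = Tensor(kernel.reshape(1, 1, 1, k))
    return conv2d(conv2d(x, kv), kh)
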