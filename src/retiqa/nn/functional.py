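"""Differentiable 2-D convolution and pooling built on im2col/col2im."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["conv2d", "max_pool2d", "global_avg_pool", "bce_with_logits"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C*kh*kw, OH*OW) patch matrix."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of `_im2col`: scatter-add patches back to image layout."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    x = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation conv, weight layout (C_out, C_in, kh, kw)."""
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {cin}")
    b = x.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    wm = weight.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wm, cols).reshape(b, cout, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    parents = [p for p in (x, weight, bias) if p is not None]

    def backward(g):
        gm = g.reshape(b, cout, oh * ow)
        grads = []
        if x.requires_grad:
            gcols = np.matmul(wm.T, gm)
            grads.append(_col2im(gcols, x.shape, kh, kw, stride, padding))
        if weight.requires_grad:
            gw = np.einsum("bon,bkn->ok", gm, cols)
            grads.append(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            grads.append(gm.sum(axis=(0, 2)).reshape(bias.shape))
        return tuple(grads)

    return Tensor._make(out, tuple(parents), backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    b, c, h, w = x.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    wins = np.empty((b, c, kernel * kernel, oh, ow), dtype=x.data.dtype)
    k = 0
    for i in range(kernel):
        for j in range(kernel):
            wins[:, :, k] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            k += 1
    arg = wins.argmax(axis=2)
    out = np.take_along_axis(wins, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gw = np.zeros((b, c, kernel * kernel, oh, ow), dtype=g.dtype)
        np.put_along_axis(gw, arg[:, :, None], g[:, :, None], axis=2)
        gw = gw.reshape(b, c, kernel, kernel, oh, ow)
        hp, wp = h + 2 * padding, w + 2 * padding
        gx = np.zeros((b, c, hp, wp), dtype=g.dtype)
        for i in range(kernel):
            for j in range(kernel):
                gx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += gw[:, :, i, j]
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        return (gx,)

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C): spatial mean per channel (the GAP layer)."""
    return x.mean(axis=(2, 3))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logit) vs {0,1} targets.

    Uses the numerically stable log-sum-exp form; gradient is
    (sigmoid(z) - q) / n, exact for any logit magnitude.
    """
    q = np.asarray(targets, dtype=np.float32)
    if q.shape != tuple(logits.shape):
        raise ValueError("bce_with_logits: logits and targets must share a shape")
    if not np.all((q == 0) | (q == 1)):
        raise ValueError("bce_with_logits: targets must be binary 0/1")
    z = logits.data
    loss = np.maximum(z, 0) - z * q + np.log1p(np.exp(-np.abs(z)))
    out = np.asarray(loss.mean(), dtype=np.float32)
    n = float(q.size)

    def backward(g):
        p = 1.0 / (1.0 + np.exp(-z))
        return (g * (p - q) / n,)

    return Tensor._make(out, (logits,), backward)
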