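"""Minimal NumPy neural-network primitives used by the segmentation model.

Everything operates on NHWC arrays (batch, height, width, channels).
Convolutions are lowered to one matrix product per layer via im2col, so the
heavy lifting happens inside BLAS; backward passes are written out explicitly
(no autograd).  All primitives are pure functions of their inputs, which is
what makes training bit-reproducible for fixed seeds on a fixed BLAS.

The default compute dtype is float32; float64 is supported so the whole
network can be checked against finite differences in tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "im2col",
    "col2im",
    "conv_forward",
    "conv_backward",
    "maxpool_forward",
    "maxpool_backward",
    "avgpool_forward",
    "avgpool_backward",
    "upsample_nearest",
    "upsample_nearest_backward",
    "upsample_linear2",
    "upsample_linear2_backward",
    "relu",
    "relu_backward",
    "sigmoid",
    "AdamState",
]


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Lower (N, H, W, C) to the (N*H*W, k*k*C) patch matrix ('same' padding)."""
    if k == 1:
        return x.reshape(-1, x.shape[-1])
    p = k // 2
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C) -> (N*H*W, k*k*C)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, k * k * c)


def col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: fold patch gradients back onto the input grid."""
    n, h, w, c = shape
    if k == 1:
        return dcols.reshape(n, h, w, c)
    p = k // 2
    d = dcols.reshape(n, h, w, k, k, c)
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + h, j:j + w, :] += d[:, :, :, i, j, :]
    return dxp[:, p:p + h, p:p + w, :]


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """'Same' convolution. ``w`` has shape (k, k, C_in, C_out).

    Returns ``(y, cols)``; ``cols`` is the patch matrix needed for backward.
    """
    k = w.shape[0]
    cout = w.shape[-1]
    cols = im2col(x, k)
    y = cols @ w.reshape(-1, cout) + b
    return y.reshape(*x.shape[:3], cout), cols


def conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray,
                  x_shape: tuple[int, int, int, int], need_dx: bool = True):
    """Gradients of a 'same' convolution: returns ``(dx, dw, db)``.

    ``need_dx=False`` skips the input gradient (for the first layer, whose
    input is data).
    """
    k, cout = w.shape[0], w.shape[-1]
    dyf = dy.reshape(-1, cout)
    dw = (cols.T @ dyf).reshape(w.shape)
    db = dyf.sum(axis=0)
    if not need_dx:
        return None, dw, db
    dcols = dyf @ w.reshape(-1, cout).T
    return col2im(dcols, x_shape, k), dw, db


def maxpool_forward(x: np.ndarray, p: int):
    """Non-overlapping p x p max pooling; ties resolve to the first maximum."""
    n, h, w, c = x.shape
    hp, wp = h // p, w // p
    xr = (
        x.reshape(n, hp, p, wp, p, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, hp, wp, p * p, c)
    )
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, idx


def maxpool_backward(dy: np.ndarray, idx: np.ndarray, x_shape, p: int) -> np.ndarray:
    n, h, w, c = x_shape
    hp, wp = h // p, w // p
    dxr = np.zeros((n, hp, wp, p * p, c), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
    return (
        dxr.reshape(n, hp, wp, p, p, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h, w, c)
    )


def avgpool_forward(x: np.ndarray, p: int) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // p, p, w // p, p, c).mean(axis=(2, 4))


def avgpool_backward(dy: np.ndarray, p: int) -> np.ndarray:
    scaled = dy / (p * p)
    return scaled.repeat(p, axis=1).repeat(p, axis=2)


def upsample_nearest(x: np.ndarray, p: int) -> np.ndarray:
    return x.repeat(p, axis=1).repeat(p, axis=2)


def upsample_nearest_backward(dy: np.ndarray, p: int) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // p, p, w // p, p, c).sum(axis=(2, 4))


def _up1_linear(a: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 linear interpolation along ``axis`` (half-pixel centers, edge clamp)."""
    a = np.moveaxis(a, axis, 1)
    am1 = np.concatenate([a[:, :1], a[:, :-1]], axis=1)
    ap1 = np.concatenate([a[:, 1:], a[:, -1:]], axis=1)
    out = np.empty((a.shape[0], 2 * a.shape[1], *a.shape[2:]), dtype=a.dtype)
    out[:, 0::2] = 0.25 * am1 + 0.75 * a
    out[:, 1::2] = 0.75 * a + 0.25 * ap1
    return np.moveaxis(out, 1, axis)


def _up1_linear_backward(d: np.ndarray, axis: int) -> np.ndarray:
    d = np.moveaxis(d, axis, 1)
    de = d[:, 0::2]
    do = d[:, 1::2]
    da = (0.75 * de + 0.75 * do).astype(d.dtype)
    da[:, :-1] += 0.25 * de[:, 1:]
    da[:, 0] += 0.25 * de[:, 0]
    da[:, 1:] += 0.25 * do[:, :-1]
    da[:, -1] += 0.25 * do[:, -1]
    return np.moveaxis(da, 1, axis)


def upsample_linear2(x: np.ndarray) -> np.ndarray:
    """Factor-2 bilinear upsampling of (N, H, W, C): smooth, differentiable."""
    return _up1_linear(_up1_linear(x, 1), 2)


def upsample_linear2_backward(dy: np.ndarray) -> np.ndarray:
    return _up1_linear_backward(_up1_linear_backward(dy, 2), 1)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class AdamState:
    """Adam optimizer over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
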