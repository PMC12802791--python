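"""Encoder-decoder (U-Net style) segmentation network, NumPy end to end.

The network maps a binary stent-marker mask to a per-pixel clot probability
map of the same size.  It is a compact U-Net: an encoder whose stages halve
the spatial size and (up to a cap) double the filter count, a mirrored
decoder with skip concatenations, and a sigmoid head.  Two small departures
from the textbook layout keep desk-scale CPU training cheap without giving up
resolution:

* an average-pooling **stem** (factor ``stem_pool``) moves the convolutional
  core to a coarser grid while preserving sub-pixel marker-displacement
  information in fractional occupancy values, and
* the final logits are **linearly upsampled** back to the input grid, so the
  0.5-probability boundary lands between coarse cells instead of on blocky
  nearest-neighbour edges.

Each decoder stage is (upsample, concatenate skip, 1x1 fuse, k x k conv).
Everything is a pure function of ``(parameters, input)``: predictions are
deterministic and serialization round trips are exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (
    conv_backward,
    conv_forward,
    maxpool_backward,
    maxpool_forward,
    relu,
    relu_backward,
    sigmoid,
)
from .io import config_fingerprint

__all__ = [
    "UNetConfig",
    "NetworkParameters",
    "build_unet",
    "predict",
    "forward",
    "backward",
    "save_params",
    "load_params",
]

#: Probabilities returned by :func:`predict` are clipped into this open interval.
PROB_EPS = 1e-7


@dataclass(frozen=True)
class UNetConfig:
    """Architecture knobs.

    ``depth`` counts pooling stages inside the core; filters at stage ``i``
    are ``min(base_filters * 2**i, channel_cap)``.  ``stem_pool`` (a power of
    two; 1 disables it) is the input-grid reduction described in the module
    docstring.  Valid input sides are multiples of
    ``stem_pool * pool_size**depth``.
    """

    depth: int = 3
    base_filters: int = 4
    kernel_size: int = 3
    pool_size: int = 2
    stem_pool: int = 2
    up_mode: str = "nearest"  # or "transposed"
    activation: str = "relu"
    channel_cap: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1 or self.channel_cap < self.base_filters:
            raise ValueError("need 1 <= base_filters <= channel_cap")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.stem_pool < 1 or (self.stem_pool & (self.stem_pool - 1)):
            raise ValueError("stem_pool must be a power of two")
        if self.up_mode not in ("nearest", "transposed"):
            raise ValueError("up_mode must be 'nearest' or 'transposed'")
        if self.activation != "relu":
            raise ValueError("only 'relu' hidden activation is supported")

    @property
    def stride(self) -> int:
        """Required divisor of the input side."""
        return self.stem_pool * self.pool_size**self.depth

    def filters(self) -> list[int]:
        return [min(self.base_filters * 2**i, self.channel_cap) for i in range(self.depth + 1)]


@dataclass
class NetworkParameters:
    """Weight collection plus the config that shaped it.

    ``train_fingerprint`` is a short hash of the training configuration that
    produced the weights (None for a freshly initialized network).
    """

    config: UNetConfig
    arrays: dict[str, np.ndarray]
    train_fingerprint: str | None = None

    @property
    def num_params(self) -> int:
        return int(sum(a.size for a in self.arrays.values()))

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(config_fingerprint(self.config).encode())
        for name in sorted(self.arrays):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.arrays[name]).tobytes())
        return h.hexdigest()

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            config=self.config,
            arrays={k: v.copy() for k, v in self.arrays.items()},
            train_fingerprint=self.train_fingerprint,
        )


def _param_shapes(cfg: UNetConfig) -> dict[str, tuple[int, ...]]:
    """Canonical parameter names and shapes, in creation order."""
    k, p = cfg.kernel_size, cfg.pool_size
    f = cfg.filters()
    shapes: dict[str, tuple[int, ...]] = {}
    cin = 1
    for i in range(cfg.depth):
        shapes[f"enc{i}_w"] = (k, k, cin, f[i])
        shapes[f"enc{i}_b"] = (f[i],)
        cin = f[i]
    shapes["bott_w"] = (k, k, f[cfg.depth - 1], f[cfg.depth])
    shapes["bott_b"] = (f[cfg.depth],)
    for i in reversed(range(cfg.depth)):
        up_in = f[i + 1]
        if cfg.up_mode == "transposed":
            shapes[f"up{i}_w"] = (p, p, up_in, f[i])
            shapes[f"up{i}_b"] = (f[i],)
            up_out = f[i]
        else:
            up_out = up_in
        shapes[f"fuse{i}_w"] = (1, 1, up_out + f[i], f[i])
        shapes[f"fuse{i}_b"] = (f[i],)
        shapes[f"dec{i}_w"] = (k, k, f[i], f[i])
        shapes[f"dec{i}_b"] = (f[i],)
    shapes["head_w"] = (1, 1, f[0], 1)
    shapes["head_b"] = (1,)
    return shapes


def build_unet(cfg: UNetConfig, seed: int | None = None,
               dtype: np.dtype = np.float32) -> NetworkParameters:
    """He-normal initialization, deterministic for a fixed ``(cfg, seed)``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    arrays: dict[str, np.ndarray] = {}
    for name, shape in _param_shapes(cfg).items():
        if name.endswith("_b"):
            arrays[name] = np.zeros(shape, dtype=dtype)
        else:
            fan_in = int(np.prod(shape[:-1]))
            std = np.sqrt(2.0 / fan_in)
            arrays[name] = (std * rng.standard_normal(shape)).astype(dtype)
    return NetworkParameters(config=cfg, arrays=arrays)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _transposed_forward(x, w, b, p):
    n, h, wdt, cin = x.shape
    cout = w.shape[-1]
    xf = x.reshape(-1, cin)
    y = np.zeros((n, p * h, p * wdt, cout), dtype=x.dtype)
    for di in range(p):
        for dj in range(p):
            y[:, di::p, dj::p, :] = (xf @ w[di, dj]).reshape(n, h, wdt, cout)
    return y + b


def _transposed_backward(dy, x, w, p):
    n, h, wdt, cin = x.shape
    cout = w.shape[-1]
    xf = x.reshape(-1, cin)
    dw = np.zeros_like(w)
    dx = np.zeros_like(x)
    db = dy.sum(axis=(0, 1, 2))
    dxf = dx.reshape(-1, cin)
    for di in range(p):
        for dj in range(p):
            dyf = dy[:, di::p, dj::p, :].reshape(-1, cout)
            dw[di, dj] = xf.T @ dyf
            dxf += dyf @ w[di, dj].T
    return dx, dw, db


def forward(params: NetworkParameters, x: np.ndarray, train: bool = False):
    """Compute logits for a (N, H, W) or (H, W) input.

    Returns ``(logits, cache)``; ``cache`` is None unless ``train`` is True,
    in which case it holds what :func:`backward` needs.
    """
    cfg = params.config
    arr = params.arrays
    dtype = arr["head_w"].dtype
    x = np.asarray(x)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"expected (N, H, W) or (H, W) input, got shape {x.shape}")
    n, h, w = x.shape
    if h % cfg.stride or w % cfg.stride:
        raise ValueError(
            f"input sides must be divisible by stem_pool*pool_size**depth = {cfg.stride}, "
            f"got {h}x{w}"
        )
    a = x.astype(dtype)[..., None]
    if cfg.stem_pool > 1:
        a = _nn.avgpool_forward(a, cfg.stem_pool)

    cache: dict | None = {} if train else None
    skips = []
    for i in range(cfg.depth):
        y, cols = conv_forward(a, arr[f"enc{i}_w"], arr[f"enc{i}_b"])
        y = relu(y)
        if train:
            cache[f"enc{i}"] = (cols, a.shape, y)
        skips.append(y)
        a, idx = maxpool_forward(y, cfg.pool_size)
        if train:
            cache[f"pool{i}"] = (idx, y.shape)

    y, cols = conv_forward(a, arr["bott_w"], arr["bott_b"])
    a = relu(y)
    if train:
        cache["bott"] = (cols, (a.shape[0], a.shape[1], a.shape[2],
                                arr["bott_w"].shape[2]), a)

    for i in reversed(range(cfg.depth)):
        if cfg.up_mode == "nearest":
            up = _nn.upsample_nearest(a, cfg.pool_size)
            if train:
                cache[f"up{i}"] = ("nearest", a.shape, None)
        else:
            up = _transposed_forward(a, arr[f"up{i}_w"], arr[f"up{i}_b"], cfg.pool_size)
            if train:
                cache[f"up{i}"] = ("transposed", a.shape, a)
        cat = np.concatenate([up, skips[i]], axis=-1)
        if train:
            cache[f"cat{i}"] = up.shape[-1]
        y, cols = conv_forward(cat, arr[f"fuse{i}_w"], arr[f"fuse{i}_b"])
        y = relu(y)
        if train:
            cache[f"fuse{i}"] = (cols, cat.shape, y)
        z, cols2 = conv_forward(y, arr[f"dec{i}_w"], arr[f"dec{i}_b"])
        a = relu(z)
        if train:
            cache[f"dec{i}"] = (cols2, y.shape, a)

    z, colsh = conv_forward(a, arr["head_w"], arr["head_b"])
    if train:
        cache["head"] = (colsh, a.shape)
    logits = z[..., 0]
    for _ in range(int(np.log2(cfg.stem_pool))):
        logits = _nn.upsample_linear2(logits[..., None])[..., 0]
    if single:
        logits = logits[0]
    return logits, cache


def backward(params: NetworkParameters, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    """Parameter gradients given the gradient of the loss w.r.t. the logits."""
    cfg = params.config
    arr = params.arrays
    dz = np.asarray(dlogits)
    if dz.ndim == 2:
        dz = dz[None]
    for _ in range(int(np.log2(cfg.stem_pool))):
        dz = _nn.upsample_linear2_backward(dz[..., None])[..., 0]
    d = dz[..., None].astype(arr["head_w"].dtype)

    grads: dict[str, np.ndarray] = {}
    cols, ash = cache["head"]
    d, grads["head_w"], grads["head_b"] = conv_backward(d, cols, arr["head_w"], ash)

    dskips: list[np.ndarray | None] = [None] * cfg.depth
    for i in range(cfg.depth):  # decoder levels, shallowest was executed last
        cols2, yshape, aout = cache[f"dec{i}"]
        d = relu_backward(d, aout)
        d, grads[f"dec{i}_w"], grads[f"dec{i}_b"] = conv_backward(
            d, cols2, arr[f"dec{i}_w"], yshape
        )
        cols, catshape, yfuse = cache[f"fuse{i}"]
        d = relu_backward(d, yfuse)
        d, grads[f"fuse{i}_w"], grads[f"fuse{i}_b"] = conv_backward(
            d, cols, arr[f"fuse{i}_w"], catshape
        )
        uch = cache[f"cat{i}"]
        dup, dskips[i] = d[..., :uch], d[..., uch:]
        mode, ashape, aup = cache[f"up{i}"]
        if mode == "nearest":
            d = _nn.upsample_nearest_backward(dup, cfg.pool_size)
        else:
            d, grads[f"up{i}_w"], grads[f"up{i}_b"] = _transposed_backward(
                dup, aup, arr[f"up{i}_w"], cfg.pool_size
            )

    cols, ash, ybott = cache["bott"]
    d = relu_backward(d, ybott)
    d, grads["bott_w"], grads["bott_b"] = conv_backward(d, cols, arr["bott_w"], ash)

    for i in reversed(range(cfg.depth)):
        idx, yshape = cache[f"pool{i}"]
        d = maxpool_backward(d, idx, yshape, cfg.pool_size)
        d = d + dskips[i]
        cols, ash, yenc = cache[f"enc{i}"]
        d = relu_backward(d, yenc)
        d, grads[f"enc{i}_w"], grads[f"enc{i}_b"] = conv_backward(
            d, cols, arr[f"enc{i}_w"], ash, need_dx=(i > 0)
        )
    return grads


def predict(params: NetworkParameters, dot_mask: np.ndarray) -> np.ndarray:
    """Clot probability map in the open interval (0, 1), same spatial shape.

    A pure, deterministic function of ``(params, dot_mask)``.
    """
    logits, _ = forward(params, dot_mask, train=False)
    return np.clip(sigmoid(logits), PROB_EPS, 1.0 - PROB_EPS)


# ---------------------------------------------------------------------------
# serialization — single .npz container with embedded config
# ---------------------------------------------------------------------------


def save_params(params: NetworkParameters, path: str | Path) -> None:
    meta = {
        "config": dataclasses.asdict(params.config),
        "train_fingerprint": params.train_fingerprint,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"param::{k}": v for k, v in params.arrays.items()},
    )


def load_params(path: str | Path) -> NetworkParameters:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = UNetConfig(**meta["config"])
        arrays = {}
        for name in _param_shapes(cfg):
            key = f"param::{name}"
            if key not in data:
                raise ValueError(f"{path}: missing parameter {name} for stored config")
            arrays[name] = data[key]
    return NetworkParameters(
        config=cfg, arrays=arrays, train_fingerprint=meta["train_fingerprint"]
    )
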