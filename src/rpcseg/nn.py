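"""Minimal encoder-decoder segmentation network in pure numpy.

A compact U-Net: two 2x-downsampling encoder stages, a bottleneck, and a
decoder with skip concatenations, ending in a 1x1 convolution that emits one
logit plane per class.  Convolutions are 3x3, stride 1, same padding,
computed channels-last as nine shifted GEMMs (one per kernel tap), which maps
well onto BLAS on a single CPU; training uses Adam on a per-channel
sigmoid + binary cross-entropy loss with an ignore-weight plane.

Everything is deterministic given the initialization seed: there is no
dropout or batch normalization, and all randomness flows through explicit
``numpy.random.Generator`` objects.  Arrays are (N, H, W, C) throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# functional layers (forward returns (y, cache); backward consumes cache)
# ---------------------------------------------------------------------------

def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution; ``x`` is (N,H,W,C), ``w`` is (3,3,C,Co)."""
    n, h, wd, c = x.shape
    xp = np.zeros((n, h + 2, wd + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1] = x
    y = np.empty((n, h, wd, w.shape[-1]), dtype=x.dtype)
    y[:] = b
    for i in range(3):
        for j in range(3):
            y += xp[:, i: i + h, j: j + wd] @ w[i, j]
    return y, (xp, w)


def conv3x3_backward(dy: np.ndarray, cache):
    xp, w = cache
    n, h, wd, co = dy.shape
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            patch = xp[:, i: i + h, j: j + wd]
            dw[i, j] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i: i + h, j: j + wd] += dy @ w[i, j].T
    db = dy.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1], dw, db


def conv1x1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, (x, w)


def conv1x1_backward(dy: np.ndarray, cache):
    x, w = cache
    dw = np.tensordot(x, dy, axes=([0, 1, 2], [0, 1, 2]))
    db = dy.sum(axis=(0, 1, 2))
    return dy @ w.T, dw, db


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, mask: np.ndarray):
    return dy * mask


def maxpool2_forward(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache):
    idx, (n, h, w, c) = cache
    dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return np.ascontiguousarray(dx).reshape(n, h, w, c)


def upsample2_forward(x: np.ndarray):
    return x.repeat(2, axis=1).repeat(2, axis=2), x.shape


def upsample2_backward(dy: np.ndarray, x_shape):
    n, h, w, c = x_shape
    return dy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted mean per-pixel, per-channel binary cross-entropy.

    ``weights`` is an (n,h,w,1) plane; ignore pixels carry weight 0.  The
    loss is the weight-normalized mean over channels and weighted pixels; the
    returned gradient is w.r.t. the logits.
    """
    z = logits
    bce = np.maximum(z, 0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    norm = float(weights.sum()) * z.shape[-1]
    if norm == 0:
        return 0.0, np.zeros_like(z)
    loss = float((bce * weights).sum() / norm)
    dz = ((sigmoid(z) - targets) * weights / norm).astype(z.dtype)
    return loss, dz


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetConfig:
    in_channels: int = 3
    base_channels: int = 8
    n_classes: int = 5
    dtype: str = "float32"


class SmallUNet:
    """Two-level U-Net with skip connections and per-class sigmoid outputs.

    Spatial sizes must be divisible by 4.  ``base_channels`` scales the
    capacity; the layer plan for base width C is
    ``3 -> C -> C | pool | -> 2C | pool | -> 2C | up+skip -> 2C | up+skip -> C -> n_classes``.
    """

    def __init__(self, config: NetConfig = NetConfig(), seed: int = 0):
        self.config = config
        c = config.base_channels
        dt = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)

        def he3(ci, co):
            return rng.normal(0.0, np.sqrt(2.0 / (ci * 9)), size=(3, 3, ci, co)).astype(dt)

        ci = config.in_channels
        self.params: dict[str, np.ndarray] = {
            "c1a.w": he3(ci, c), "c1a.b": np.zeros(c, dt),
            "c1b.w": he3(c, c), "c1b.b": np.zeros(c, dt),
            "c2a.w": he3(c, 2 * c), "c2a.b": np.zeros(2 * c, dt),
            "cb.w": he3(2 * c, 2 * c), "cb.b": np.zeros(2 * c, dt),
            "d2.w": he3(4 * c, 2 * c), "d2.b": np.zeros(2 * c, dt),
            "d1.w": he3(3 * c, c), "d1.b": np.zeros(c, dt),
            "out.w": rng.normal(0.0, np.sqrt(2.0 / c),
                                size=(c, config.n_classes)).astype(dt),
            "out.b": np.zeros(config.n_classes, dt),
        }

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray):
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise ValueError(f"spatial size {x.shape[1:3]} must be divisible by 4")
        p = self.params
        cache: dict[str, object] = {}
        a, cache["c1a"] = conv3x3_forward(x, p["c1a.w"], p["c1a.b"])
        a, cache["r1a"] = relu_forward(a)
        e1, cache["c1b"] = conv3x3_forward(a, p["c1b.w"], p["c1b.b"])
        e1, cache["r1b"] = relu_forward(e1)
        p1, cache["pool1"] = maxpool2_forward(e1)
        e2, cache["c2a"] = conv3x3_forward(p1, p["c2a.w"], p["c2a.b"])
        e2, cache["r2a"] = relu_forward(e2)
        p2, cache["pool2"] = maxpool2_forward(e2)
        b, cache["cb"] = conv3x3_forward(p2, p["cb.w"], p["cb.b"])
        b, cache["rb"] = relu_forward(b)
        u2, cache["up2"] = upsample2_forward(b)
        d2, cache["d2"] = conv3x3_forward(np.concatenate([u2, e2], axis=-1),
                                          p["d2.w"], p["d2.b"])
        d2, cache["rd2"] = relu_forward(d2)
        u1, cache["up1"] = upsample2_forward(d2)
        d1, cache["d1"] = conv3x3_forward(np.concatenate([u1, e1], axis=-1),
                                          p["d1.w"], p["d1.b"])
        d1, cache["rd1"] = relu_forward(d1)
        logits, cache["out"] = conv1x1_forward(d1, p["out.w"], p["out.b"])
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        c = self.config.base_channels
        g: dict[str, np.ndarray] = {}
        dd1, g["out.w"], g["out.b"] = conv1x1_backward(dlogits, cache["out"])
        dd1 = relu_backward(dd1, cache["rd1"])
        dd1_in, g["d1.w"], g["d1.b"] = conv3x3_backward(dd1, cache["d1"])
        du1, de1_skip = dd1_in[..., : 2 * c], dd1_in[..., 2 * c:]
        dd2 = upsample2_backward(du1, cache["up1"])
        dd2 = relu_backward(dd2, cache["rd2"])
        dd2_in, g["d2.w"], g["d2.b"] = conv3x3_backward(dd2, cache["d2"])
        du2, de2_skip = dd2_in[..., : 2 * c], dd2_in[..., 2 * c:]
        db = upsample2_backward(du2, cache["up2"])
        db = relu_backward(db, cache["rb"])
        dp2, g["cb.w"], g["cb.b"] = conv3x3_backward(db, cache["cb"])
        de2 = maxpool2_backward(dp2, cache["pool2"]) + de2_skip
        de2 = relu_backward(de2, cache["r2a"])
        dp1, g["c2a.w"], g["c2a.b"] = conv3x3_backward(de2, cache["c2a"])
        de1 = maxpool2_backward(dp1, cache["pool1"]) + de1_skip
        de1 = relu_backward(de1, cache["r1b"])
        da, g["c1b.w"], g["c1b.b"] = conv3x3_backward(de1, cache["c1b"])
        da = relu_backward(da, cache["r1a"])
        _, g["c1a.w"], g["c1a.b"] = conv3x3_backward(da, cache["c1a"])
        return g

    # -- inference ----------------------------------------------------------
    def predict_scores(self, patch: np.ndarray) -> np.ndarray:
        """Sigmoid class scores (H, W, n_classes) for one RGB uint8 patch."""
        x = preprocess(patch, self.config.dtype)[None]
        logits, _ = self.forward(x)
        return sigmoid(logits[0])

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "SmallUNet":
        path = Path(path)
        config = NetConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model


def preprocess(patch: np.ndarray, dtype: str = "float32") -> np.ndarray:
    """uint8 HxWx3 RGB -> centered HxWx3 float input."""
    return np.asarray(patch, dtype=dtype) / 255.0 - 0.5


class Adam:
    """Standard Adam with per-parameter moment buffers."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            gk = grads[k].astype(p.dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
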