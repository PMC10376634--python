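"""Compact fully convolutional segmentation backbone, in numpy.

The reference backbone is a tiny U-Net: a 3x3 convolution stage, one 2x2
max-pool encoder stage, nearest-neighbour upsampling with a skip
concatenation, and a 1x1 K-way probability head.  Forward and backward
passes are written directly with im2col matrix products, which is entirely
adequate at the raster sizes this package trains on and keeps the training
loop free of heavyweight dependencies.  Gradients for all the package's
losses are softmax cross-entropy gradients, so the backward pass only ever
receives ``dL/dlogits``.

Everything is deterministic: parameters are drawn from a seeded
``numpy.random.Generator`` and no operation introduces nondeterminism.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyUNet", "SGDMomentum", "softmax"]

ARCHITECTURE_ID = "tiny-unet-v1"


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patch matrix for a stride-1 'same' conv."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k) -> (B, H*W, C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, H * W, C * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Scatter-add adjoint of :func:`_im2col`."""
    B, C, H, W = x_shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(B, H, W, C, k, k)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + H, dj : dj + W] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, pad : pad + H, pad : pad + W]


class _Conv:
    """Stride-1 'same' convolution with bias."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int):
        self.name, self.c_in, self.c_out, self.k = name, c_in, c_out, k
        self.pad = k // 2

    def init_params(self, rng: np.random.Generator, params: dict) -> None:
        fan_in = self.c_in * self.k * self.k
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stages
        params[f"{self.name}.W"] = rng.normal(0.0, scale, (self.c_out, fan_in)).astype(np.float64)
        params[f"{self.name}.b"] = np.zeros(self.c_out, dtype=np.float64)

    def forward(self, x: np.ndarray, params: dict, cache: dict) -> np.ndarray:
        B, C, H, W = x.shape
        cols = _im2col(x, self.k, self.pad)
        out = cols @ params[f"{self.name}.W"].T + params[f"{self.name}.b"]
        cache[self.name] = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(B, self.c_out, H, W)

    def backward(self, dout: np.ndarray, params: dict, cache: dict, grads: dict) -> np.ndarray:
        cols, x_shape = cache[self.name]
        B, _, H, W = dout.shape
        dflat = dout.reshape(B, self.c_out, H * W).transpose(0, 2, 1)  # (B, HW, c_out)
        grads[f"{self.name}.W"] = np.einsum("bpc,bpk->ck", dflat, cols)
        grads[f"{self.name}.b"] = dflat.sum(axis=(0, 1))
        dcols = dflat @ params[f"{self.name}.W"]
        return _col2im(dcols, x_shape, self.k, self.pad)


def _maxpool2(x: np.ndarray):
    B, C, H, W = x.shape
    r = x.reshape(B, C, H // 2, 2, W // 2, 2)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)
    return out, (mask, counts)


def _maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    mask, counts = cache
    d = mask * (dout[:, :, :, None, :, None] / counts)
    B, C, H2, _, W2, _ = d.shape
    return d.reshape(B, C, H2 * 2, W2 * 2)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    B, C, H, W = dout.shape
    return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class TinyUNet:
    """Tiny encoder-decoder with a K-way softmax head.

    Layers: conv3(1->C) ReLU, pool2, conv3(C->2C) ReLU, upsample2, skip
    concat (3C), conv3(3C->C) ReLU, conv1(C->K).  Input rasters must have
    even height and width.
    """

    def __init__(self, num_classes: int, seed: int, width: int = 8, in_channels: int = 1):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        self.num_classes = int(num_classes)
        self.seed = int(seed)
        self.width = int(width)
        self.in_channels = int(in_channels)
        self.architecture_id = ARCHITECTURE_ID
        C = self.width
        self._layers = [
            _Conv("enc1", self.in_channels, C, 3),
            _Conv("enc2", C, 2 * C, 3),
            _Conv("dec1", 3 * C, C, 3),
            _Conv("head", C, self.num_classes, 1),
        ]
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, np.ndarray] = {}
        for layer in self._layers:
            layer.init_params(rng, self.params)

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray):
        """Return (logits (B,K,H,W), cache); x is (B, C_in, H, W) float."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected input of shape (B, {self.in_channels}, H, W)")
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("raster height and width must be even")
        enc1, enc2, dec1, head = self._layers
        cache: dict = {}

        a1 = enc1.forward(x, self.params, cache)
        r1 = np.maximum(a1, 0.0)
        cache["relu1"] = a1 > 0

        p1, cache["pool"] = _maxpool2(r1)
        a2 = enc2.forward(p1, self.params, cache)
        r2 = np.maximum(a2, 0.0)
        cache["relu2"] = a2 > 0

        u2 = _upsample2(r2)
        cat = np.concatenate([r1, u2], axis=1)
        a3 = dec1.forward(cat, self.params, cache)
        r3 = np.maximum(a3, 0.0)
        cache["relu3"] = a3 > 0

        logits = head.forward(r3, self.params, cache)
        return logits, cache

    def forward_probs(self, x: np.ndarray):
        logits, cache = self.forward_logits(x)
        return softmax(logits, axis=1), cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        """Gradients of all parameters given dL/dlogits."""
        enc1, enc2, dec1, head = self._layers
        grads: dict[str, np.ndarray] = {}
        C = self.width

        d3 = head.backward(dlogits, self.params, cache, grads)
        d3 = d3 * cache["relu3"]
        dcat = dec1.backward(d3, self.params, cache, grads)
        dr1_skip, du2 = dcat[:, :C], dcat[:, C:]

        d2 = _upsample2_backward(du2) * cache["relu2"]
        dp1 = enc2.backward(d2, self.params, cache, grads)
        dr1 = _maxpool2_backward(dp1, cache["pool"]) + dr1_skip

        d1 = dr1 * cache["relu1"]
        enc1.backward(d1, self.params, cache, grads)
        return grads

    # -- convenience --------------------------------------------------------

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities, channels-last (B, H, W, K)."""
        logits, _ = self.forward_logits(x)
        return softmax(logits, axis=1).transpose(0, 2, 3, 1)

    def get_state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()


class SGDMomentum:
    """Classic momentum SGD: v <- mu*v + g; w <- w - lr*v."""

    def __init__(self, params: dict, lr: float, momentum: float = 0.9):
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for k in params:
            self.velocity[k] = self.momentum * self.velocity[k] + grads[k]
            params[k] -= lr * self.velocity[k]

    def get_state(self) -> dict:
        return {k: v.copy() for k, v in self.velocity.items()}

    def set_state(self, state: dict) -> None:
        for k in self.velocity:
            self.velocity[k] = np.asarray(state[k], dtype=np.float64).copy()
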