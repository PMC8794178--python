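"""A small CNN for 150x150 cell-image classification, with explicit backprop.

The architecture is fixed by design: four 5x5 "same" convolution layers
(channel widths 16, 16, 32, 32 for single-channel input, doubled when the
input has two or more channels), each followed by ReLU and a 3x3 stride-2
max-pool; dropout (rate 0.1) in every gap between layers; a 2000-node ReLU
fully-connected layer; and a 2-node softmax output trained with binary
cross-entropy.  Spatial sizes are computed programmatically
(150 -> 74 -> 36 -> 17 -> 8 with valid 3x3/2 pooling).

Convolution and pooling run as direct numba loops (see ``_kernels``); the
dense layers are BLAS matmuls.  Optimisation is Adam (alpha 1e-4, beta1 0.9,
beta2 0.999, eps 1e-8).  All randomness (weight init, dropout, shuffling)
flows from explicit seeds, so training is reproducible on CPU.
"""

from __future__ import annotations

import math

import numpy as np

from cellchannel._kernels import (
    conv5_dw,
    conv5_forward,
    maxpool3s2_backward,
    maxpool3s2_forward,
)

KERNEL = 5
PAD = KERNEL // 2
POOL_K = 3
POOL_S = 2


def pool_out_size(n: int) -> int:
    """Output length of a valid 3x3 stride-2 max-pool over ``n`` pixels."""
    return (n - POOL_K) // POOL_S + 1


def _pad(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD)))


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padding 5x5 convolution on (B, C, H, W).  Returns (out, xpad)."""
    xp = _pad(x)
    nb, _, h, wd = x.shape
    out = np.empty((nb, w.shape[0], h, wd), dtype=np.float32)
    conv5_forward(xp, w, b, out)
    return out, xp


def conv_backward(dout: np.ndarray, xp: np.ndarray, w: np.ndarray,
                  need_dx: bool = True):
    """Gradients of a same-padding convolution.

    ``dx`` is the full correlation of ``dout`` with the flipped kernels,
    skipped for the input layer (``need_dx=False``).
    """
    dw = np.zeros_like(w)
    conv5_dw(xp, dout, dw)
    db = dout.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        w_hat = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        nb, cin = dout.shape[0], w.shape[1]
        dx = np.empty((nb, cin, dout.shape[2], dout.shape[3]), dtype=np.float32)
        conv5_forward(_pad(dout), w_hat, np.zeros(cin, np.float32), dx)
    return dx, dw, db


def maxpool_forward(x: np.ndarray):
    nb, c, h, w = x.shape
    ho, wo = pool_out_size(h), pool_out_size(w)
    out = np.empty((nb, c, ho, wo), dtype=np.float32)
    arg = np.empty((nb, c, ho, wo), dtype=np.int8)
    maxpool3s2_forward(x, out, arg)
    return out, (arg, (nb, c, h, w))


def maxpool_backward(dout: np.ndarray, cache) -> np.ndarray:
    arg, shape = cache
    dx = np.zeros(shape, dtype=np.float32)
    maxpool3s2_backward(dout, arg, dx)
    return dx


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; ``rng=None`` means inference (identity)."""
    if rng is None or rate <= 0:
        return x, None
    keep = (rng.random(x.shape, dtype=np.float32) >= rate).astype(np.float32)
    keep /= (1.0 - rate)
    return x * keep, keep


def softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """The fixed four-conv / two-FC network."""

    def __init__(self, in_channels: int, input_size: int = 150,
                 fc_nodes: int = 2000, n_classes: int = 2,
                 dropout: float = 0.1, seed: int = 0):
        widths = (16, 16, 32, 32) if in_channels == 1 else (32, 32, 64, 64)
        self.in_channels = in_channels
        self.widths = widths
        self.dropout = dropout
        self.input_size = input_size
        size = input_size
        for _ in widths:
            size = pool_out_size(size)
            if size < 1:
                raise ValueError("input too small for four pooling stages")
        self.final_size = size
        self.flat_size = widths[-1] * size * size
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = in_channels
        for i, cout in enumerate(widths, start=1):
            fan_in = cin * KERNEL * KERNEL
            self.params[f"w{i}"] = (rng.standard_normal(
                (cout, cin, KERNEL, KERNEL)) * math.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        self.params["wf1"] = (rng.standard_normal((self.flat_size, fc_nodes))
                              * math.sqrt(2.0 / self.flat_size)).astype(np.float32)
        self.params["bf1"] = np.zeros(fc_nodes, dtype=np.float32)
        self.params["wf2"] = (rng.standard_normal((fc_nodes, n_classes))
                              * math.sqrt(2.0 / fc_nodes)).astype(np.float32)
        self.params["bf2"] = np.zeros(n_classes, dtype=np.float32)

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Class probabilities for a (B, C, H, W) batch; ``rng`` enables
        dropout (training mode)."""
        h = np.ascontiguousarray(x, dtype=np.float32)
        cache: list = []
        for i in range(1, 5):
            out, xp = conv_forward(h, self.params[f"w{i}"], self.params[f"b{i}"])
            relu_mask = out > 0
            out *= relu_mask
            pooled, pcache = maxpool_forward(out)
            dropped, dmask = dropout_forward(pooled, self.dropout, rng)
            cache.append((xp, relu_mask, pcache, dmask))
            h = dropped
        bsz = h.shape[0]
        flat = h.reshape(bsz, -1)
        z1 = flat @ self.params["wf1"] + self.params["bf1"]
        r1 = z1 > 0
        a1 = z1 * r1
        a1d, dmask_fc = dropout_forward(a1, self.dropout, rng)
        logits = a1d @ self.params["wf2"] + self.params["bf2"]
        probs = softmax_rows(logits)
        cache.append((flat, r1, a1d, dmask_fc, h.shape))
        return probs, cache

    def backward(self, probs: np.ndarray, y: np.ndarray, cache) -> dict:
        """Gradients of the mean cross-entropy w.r.t. every parameter."""
        bsz = probs.shape[0]
        dlogits = probs.astype(np.float32)
        dlogits[np.arange(bsz), y] -= 1.0
        dlogits /= bsz
        flat, r1, a1d, dmask_fc, h_shape = cache[-1]
        grads: dict[str, np.ndarray] = {}
        grads["wf2"] = a1d.T @ dlogits
        grads["bf2"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.params["wf2"].T
        if dmask_fc is not None:
            da1 = da1 * dmask_fc
        dz1 = da1 * r1
        grads["wf1"] = flat.T @ dz1
        grads["bf1"] = dz1.sum(axis=0)
        dh = (dz1 @ self.params["wf1"].T).reshape(h_shape)
        for i in range(4, 0, -1):
            xp, relu_mask, pcache, dmask = cache[i - 1]
            if dmask is not None:
                dh = dh * dmask
            dh = maxpool_backward(dh, pcache)
            dh *= relu_mask
            dh, dw, db = conv_backward(dh, xp, self.params[f"w{i}"],
                                       need_dx=(i > 1))
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Deterministic inference (dropout off), batched."""
        out = []
        for i in range(0, len(x), batch_size):
            probs, _ = self.forward(x[i:i + batch_size], rng=None)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of softmax outputs against integer labels."""
    p = np.clip(probs[np.arange(len(y)), y], eps, 1.0)
    return float(-np.log(p).mean())
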