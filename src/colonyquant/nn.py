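"""Minimal numpy neural-network engine used by the trainable pipeline stages.

Implements exactly the pieces the colony pipeline needs — 2-D convolution via
im2col, ReLU, 2x2 max pooling, nearest-neighbour upsampling, fully connected
layers, SGD with momentum and weight decay, binary cross-entropy with logits
and categorical cross-entropy.  All layers cache what their backward pass
needs; gradients are checked against finite differences in the test suite.

Everything is float32 and seeded: constructing a network from the same
``numpy.random.Generator`` state yields bit-identical weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32  # switchable to float64 for numerical checks

__all__ = [
    "DTYPE",
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Linear",
    "Flatten",
    "SGD",
    "bce_with_logits",
    "softmax",
    "softmax_cross_entropy",
    "sigmoid",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv2d:
    """Same-padded stride-1 convolution over (N, C, H, W) arrays."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self.k = k
        self.pad = k // 2
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N, H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=self.weight.value.dtype)
        wm = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = cols @ wm.T + self.bias.value
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.pad
        c_out = dout.shape[1]
        dflat = dout.reshape(n, c_out, h * w).transpose(0, 2, 1)  # N, HW, c_out
        wm = self.weight.value.reshape(c_out, -1)
        dw = np.einsum("nij,nik->jk", dflat, cols, optimize=True)  # (c_out, C*k*k)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        self.bias.grad += dflat.sum(axis=(0, 1))
        dcols = (dflat @ wm).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def __init__(self):
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : h2 * 2, : w2 * 2]
        blocks = xt.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h2, w2, 4)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        n, c, h, w = xshape
        h2, w2 = h // 2, w // 2
        dblocks = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=-1)
        dx_t = dblocks.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(xshape, dtype=dout.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = dx_t.reshape(n, c, h2 * 2, w2 * 2)
        return dx


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weight = Param(w)
        self.bias = Param(np.zeros(n_out))
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value.T


class SGD:
    """SGD with momentum and decoupled-from-schedule weight decay.

    ``groups`` is an ordered list of parameter lists; ``step`` takes one
    learning rate per group so differential learning rates across network
    thirds are a single call.
    """

    def __init__(self, groups: list[list[Param]], momentum: float = 0.9, weight_decay: float = 0.0):
        self.groups = groups
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [[np.zeros_like(p.value) for p in g] for g in groups]

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g:
                p.grad[...] = 0.0

    def step(self, lrs) -> None:
        lrs = np.broadcast_to(np.asarray(lrs, dtype=np.float64), (len(self.groups),))
        for g, vel, lr in zip(self.groups, self._vel, lrs):
            if lr == 0.0:
                continue
            for p, v in zip(g, vel):
                grad = p.grad + self.weight_decay * p.value
                v *= self.momentum
                v -= lr * grad
                p.value += v


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits and its gradient w.r.t. logits.

    ``pos_weight`` scales the positive-class term, countering foreground/
    background imbalance in segmentation targets.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    softplus = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    if pos_weight == 1.0:
        loss = softplus
        grad = (sigmoid(z) - y) / z.size
    else:
        sp_neg = np.maximum(-z, 0) + np.log1p(np.exp(-np.abs(z)))  # log(1+e^-z)
        sp_pos = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))  # log(1+e^z)
        loss = pos_weight * y * sp_neg + (1.0 - y) * sp_pos
        s = sigmoid(z)
        grad = ((1.0 - y) * s - pos_weight * y * (1.0 - s)) / z.size
    return float(loss.mean()), grad.astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over integer labels, plus logit gradient."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)
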