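"""Layers with forward/backward passes, NHWC layout throughout.

Convolution is computed as nine shifted ``tensordot`` contractions (one per
kernel tap) instead of an explicit im2col buffer: for 3x3 kernels this is
matmul-bound, allocation-light, and its transpose (the backward pass) falls
out symmetrically. Zero padding realises the "same" spatial contract the
architecture's 256→128→64→32 ladder requires.

Weight layers may *share* their parameter and gradient arrays with another
layer instance (tied weights across CNN branches): gradients accumulate with
``+=`` and are zeroed once per optimizer step, so sharing needs no special
casing anywhere else.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv3x3", "ReLU", "MaxPool2", "AvgPool2", "Dropout",
           "Flatten", "Dense", "softmax", "softmax_cross_entropy"]


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(array, grad) pairs; empty for parameter-free layers."""
        return []

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero ("same") padding, NHWC.

    ``W`` has shape ``(3, 3, c_in, c_out)``. Pass ``share_with`` to tie the
    weights (and gradient accumulators) to another instance.
    """

    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None,
                 share_with: "Conv3x3 | None" = None):
        self.c_in, self.c_out = c_in, c_out
        if share_with is not None:
            if (share_with.c_in, share_with.c_out) != (c_in, c_out):
                raise ValueError("cannot tie conv layers of different shape")
            self.W, self.b = share_with.W, share_with.b
            self.dW, self.db = share_with.dW, share_with.db
        else:
            if rng is None:
                raise ValueError("need an rng (or share_with) to init Conv3x3")
            self.W = _he_init(rng, (3, 3, c_in, c_out), fan_in=9 * c_in)
            self.b = np.zeros(c_out, dtype=np.float32)
            self.dW = np.zeros_like(self.W)
            self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        n, h, w, _ = x.shape
        self._xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.tile(self.b.astype(x.dtype), (n, h, w, 1))
        for di in range(3):
            for dj in range(3):
                patch = self._xp[:, di:di + h, dj:dj + w, :]
                y += np.tensordot(patch, self.W[di, dj], axes=([3], [0]))
        return y

    def backward(self, dout):
        n, h, w, _ = dout.shape
        dxp = np.zeros_like(self._xp)
        self.db += dout.sum(axis=(0, 1, 2))
        for di in range(3):
            for dj in range(3):
                patch = self._xp[:, di:di + h, dj:dj + w, :]
                self.dW[di, dj] += np.tensordot(patch, dout,
                                                axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di:di + h, dj:dj + w, :] += np.tensordot(
                    dout, self.W[di, dj], axes=([3], [1]))
        self._xp = None
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Ties resolve to the first window element."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xw = xr.reshape(n, h // 2, w // 2, c, 4)
        self._arg = xw.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xw, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._shape
        dw = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dw, self._arg[..., None], dout[..., None], axis=-1)
        dx = dw.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(n, h, w, c)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._shape
        dx = np.broadcast_to(dout[:, :, None, :, None, :] / 4.0,
                             (n, h // 2, 2, w // 2, 2, c))
        return dx.reshape(n, h, w, c)


class Dropout(Layer):
    """Inverted dropout; identity at inference (``train=False``)."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None,
                 share_with: "Dense | None" = None):
        self.n_in, self.n_out = n_in, n_out
        if share_with is not None:
            self.W, self.b = share_with.W, share_with.b
            self.dW, self.db = share_with.dW, share_with.db
        else:
            if rng is None:
                raise ValueError("need an rng (or share_with) to init Dense")
            self.W = _he_init(rng, (n_in, n_out), fan_in=n_in)
            self.b = np.zeros(n_out, dtype=np.float32)
            self.dW = np.zeros_like(self.W)
            self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``labels`` are integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
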