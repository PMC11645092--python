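"""Feed-forward layers with explicit forward/backward passes (float64)."""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: subclasses cache what backward needs during forward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, name: str = "linear"):
        self.W = Param(f"{name}.W", glorot(rng, (in_features, out_features), in_features, out_features))
        self.b = Param(f"{name}.b", np.zeros(out_features))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs an rng per forward call."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Conv2d(Layer):
    """3x3 (or kxk) convolution, stride 1, same padding, NCHW layout."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.W = Param(f"{name}.W", glorot(rng, (out_ch, in_ch, kernel, kernel), fan_in, out_ch * kernel * kernel))
        self.b = Param(f"{name}.b", np.zeros(out_ch))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # windows: (B, C, H, W, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        self._win = win
        self._x_shape = x.shape
        out = np.einsum("bchwij,ocij->bohw", win, self.W.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        p, k = self.pad, self.k
        self.W.grad += np.einsum("bchwij,bohw->ocij", self._win, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                # dxp[:, :, i:i+h, j:j+w] += sum_o dout[:, o] * W[o, :, i, j]
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "bohw,oc->bchw", dout, self.W.value[:, :, i, j], optimize=True
                )
        return dxp[:, :, p : p + h, p : p + w]


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, :, : 2 * h2, : 2 * w2].reshape(b, c, h2, 2, w2, 2)
        flat = xv.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((b, c, h2, w2, 4))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dflat.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, 2 * h2, 2 * w2)
        )
        return dx


class GlobalAvgPool(Layer):
    """Mean over the spatial axes: (B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None], (b, c, h, w)) / (h * w)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample binary cross-entropy and its gradient w.r.t. the logit.

    Uses the numerically stable log(1 + exp(-|z|)) form; the gradient is
    sigmoid(z) - y, the quantity every per-sample attribution path reuses.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return loss, sigmoid(z) - y
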