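"""LSTM layer with variable-length masking and truncated-nowhere BPTT.

Sequences are padded to a common length T and accompanied by integer lengths.
At padded steps the hidden and cell state are carried through unchanged, so
``h[:, -1]`` is every sequence's true final hidden state regardless of its
length — the quantity the scanpath branch feeds to its linear head.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, glorot, sigmoid


class LSTM(Layer):
    """Single LSTM layer, gate order (input, forget, cell, output)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator, name: str = "lstm"):
        self.input_size = input_size
        self.hidden_size = hidden_size
        h = hidden_size
        self.Wx = Param(f"{name}.Wx", glorot(rng, (input_size, 4 * h), input_size, h))
        self.Wh = Param(f"{name}.Wh", glorot(rng, (h, 4 * h), h, h))
        self.b = Param(f"{name}.b", np.zeros(4 * h))
        # forget-gate bias of 1: standard trick for gradient flow early in training
        self.b.value[h : 2 * h] = 1.0

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, lengths: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, T, input_size); lengths: (B,) ints >= 1.  Returns h: (B, T, H)."""
        B, T, _ = x.shape
        H = self.hidden_size
        mask = (np.arange(T)[None, :] < np.asarray(lengths)[:, None]).astype(np.float64)
        h_prev = np.zeros((B, H))
        c_prev = np.zeros((B, H))
        self._cache = []
        self._x = x
        self._mask = mask
        hs = np.zeros((B, T, H))
        for t in range(T):
            m = mask[:, t : t + 1]
            z = x[:, t] @ self.Wx.value + h_prev @ self.Wh.value + self.b.value
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_tilde = f * c_prev + i * g
            tc = np.tanh(c_tilde)
            h_tilde = o * tc
            c_t = m * c_tilde + (1.0 - m) * c_prev
            h_t = m * h_tilde + (1.0 - m) * h_prev
            self._cache.append((h_prev, c_prev, i, f, g, o, tc, m))
            hs[:, t] = h_t
            h_prev, c_prev = h_t, c_t
        return hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """dout: (B, T, H) gradient w.r.t. the full hidden sequence."""
        B, T, _ = self._x.shape
        H = self.hidden_size
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc, m = self._cache[t]
            dh = dout[:, t] + dh_next
            dc = dc_next
            dh_tilde = m * dh
            dh_carry = (1.0 - m) * dh
            dc_tilde = m * dc
            dc_carry = (1.0 - m) * dc
            do = dh_tilde * tc
            dc_tilde = dc_tilde + dh_tilde * o * (1.0 - tc * tc)
            df = dc_tilde * c_prev
            di = dc_tilde * g
            dg = dc_tilde * i
            dc_prev = dc_tilde * f + dc_carry
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += self._x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T + dh_carry
            dc_next = dc_prev
        return dx
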