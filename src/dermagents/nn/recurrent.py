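"""Recurrent sequence encoders (GRU/LSTM) with masked batched BPTT.

Inputs are padded embedding tensors ``(N, T, D)`` with a boolean mask of
real positions; the returned encoding is the hidden state after the last
real step of each sequence. ``Bidirectional`` concatenates a forward and a
per-sequence-reversed pass.
"""

from __future__ import annotations

import numpy as np

from .layers import Module


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class GRU(Module):
    """Single-direction gated recurrent unit; gate order (z, r, n)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.d_hidden = d_in, d_hidden
        sx = np.sqrt(1.0 / d_in)
        sh = np.sqrt(1.0 / d_hidden)
        self.Wx = self.add_param("Wx", rng.normal(0.0, sx, size=(d_in, 3 * d_hidden)))
        self.Wh = self.add_param("Wh", rng.normal(0.0, sh, size=(d_hidden, 3 * d_hidden)))
        self.b = self.add_param("b", np.zeros(3 * d_hidden))
        self._cache: list[tuple] | None = None

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        h = np.zeros((n, self.d_hidden))
        dh = self.d_hidden
        cache = []
        for step in range(t):
            xt = x[:, step, :]
            m = mask[:, step].astype(np.float64)[:, None]
            a = xt @ self.Wx + self.b
            hh = h @ self.Wh
            z = _sigmoid(a[:, :dh] + hh[:, :dh])
            r = _sigmoid(a[:, dh : 2 * dh] + hh[:, dh : 2 * dh])
            hn = hh[:, 2 * dh :]
            ncand = np.tanh(a[:, 2 * dh :] + r * hn)
            h_new = (1.0 - z) * ncand + z * h
            h_next = m * h_new + (1.0 - m) * h
            cache.append((xt, h, z, r, ncand, hn, m))
            h = h_next
        self._cache = cache
        self._x_shape = x.shape
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        dh = dh.copy()
        dx = np.zeros(self._x_shape)
        dhd = self.d_hidden
        for step in range(len(self._cache) - 1, -1, -1):
            xt, h_prev, z, r, ncand, hn, m = self._cache[step]
            dh_new = dh * m
            dh_prev = dh * (1.0 - m)
            dz = dh_new * (h_prev - ncand) * z * (1.0 - z)
            dn = dh_new * (1.0 - z) * (1.0 - ncand**2)
            dr = dn * hn * r * (1.0 - r)
            dhn = dn * r
            da = np.concatenate([dz, dr, dn], axis=1)
            dhh = np.concatenate([dz, dr, dhn], axis=1)
            self._grads["Wx"] += xt.T @ da
            self._grads["Wh"] += h_prev.T @ dhh
            self._grads["b"] += da.sum(axis=0)
            dx[:, step, :] = da @ self.Wx.T
            dh = dh_prev + dh_new * z + dhh @ self.Wh.T
        return dx


class LSTM(Module):
    """Single-direction LSTM; gate order (i, f, g, o)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.d_hidden = d_in, d_hidden
        sx = np.sqrt(1.0 / d_in)
        sh = np.sqrt(1.0 / d_hidden)
        self.Wx = self.add_param("Wx", rng.normal(0.0, sx, size=(d_in, 4 * d_hidden)))
        self.Wh = self.add_param("Wh", rng.normal(0.0, sh, size=(d_hidden, 4 * d_hidden)))
        self.b = self.add_param("b", np.zeros(4 * d_hidden))
        self._cache: list[tuple] | None = None

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        dh = self.d_hidden
        h = np.zeros((n, dh))
        c = np.zeros((n, dh))
        cache = []
        for step in range(t):
            xt = x[:, step, :]
            m = mask[:, step].astype(np.float64)[:, None]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(gates[:, :dh])
            f = _sigmoid(gates[:, dh : 2 * dh])
            g = np.tanh(gates[:, 2 * dh : 3 * dh])
            o = _sigmoid(gates[:, 3 * dh :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            h_next = m * h_new + (1.0 - m) * h
            c_next = m * c_new + (1.0 - m) * c
            cache.append((xt, h, c, i, f, g, o, c_new, tanh_c, m))
            h, c = h_next, c_next
        self._cache = cache
        self._x_shape = x.shape
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        dh = dh.copy()
        dc = np.zeros_like(dh)
        dx = np.zeros(self._x_shape)
        for step in range(len(self._cache) - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = self._cache[step]
            dh_new = dh * m
            dh_prev = dh * (1.0 - m)
            dc_new = dc * m + dh_new * o * (1.0 - tanh_c**2)
            dc_prev = dc * (1.0 - m)
            do = dh_new * tanh_c * o * (1.0 - o)
            di = dc_new * g * i * (1.0 - i)
            df = dc_new * c_prev * f * (1.0 - f)
            dg = dc_new * i * (1.0 - g**2)
            dgates = np.concatenate([di, df, dg, do], axis=1)
            self._grads["Wx"] += xt.T @ dgates
            self._grads["Wh"] += h_prev.T @ dgates
            self._grads["b"] += dgates.sum(axis=0)
            dx[:, step, :] = dgates @ self.Wx.T
            dh = dh_prev + dgates @ self.Wh.T
            dc = dc_prev + dc_new * f
        return dx


def _reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``lengths[i]`` timesteps, keeping padding last."""
    out = np.zeros_like(x)
    for idx, length in enumerate(lengths):
        out[idx, :length] = x[idx, length - 1 :: -1]
    return out


class Bidirectional(Module):
    """Concatenate forward and reversed passes of two independent encoders."""

    def __init__(self, forward_rnn: Module, backward_rnn: Module) -> None:
        super().__init__()
        self.fwd = self.add_child("fwd", forward_rnn)
        self.bwd = self.add_child("bwd", backward_rnn)
        self.d_hidden = forward_rnn.d_hidden + backward_rnn.d_hidden

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        lengths = mask.sum(axis=1).astype(int)
        self._lengths = lengths
        h_f = self.fwd.forward(x, mask)
        h_b = self.bwd.forward(_reverse_padded(x, lengths), mask)
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, dh: np.ndarray) -> np.ndarray:
        df = self.fwd.d_hidden
        dx_f = self.fwd.backward(dh[:, :df])
        dx_b = self.bwd.backward(dh[:, df:])
        return dx_f + _reverse_padded(dx_b, self._lengths)
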