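"""Feed-forward layers with explicit reverse-mode gradients.

Conventions: images are channel-last ``(N, H, W, C)`` float64 arrays; every
layer caches what its backward pass needs on ``forward`` and accumulates
parameter gradients in place (call :meth:`Module.zero_grad` between steps).
"""

from __future__ import annotations

import numpy as np


class Module:
    """Base class: parameter/gradient registry with nested children.

    Parameter and gradient arrays are stable objects (updated in place), so
    an optimizer may hold direct references to them.
    """

    def __init__(self) -> None:
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}
        self._children: dict[str, Module] = {}

    # -- registry ---------------------------------------------------------
    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float64)
        self._params[name] = arr
        self._grads[name] = np.zeros_like(arr)
        return arr

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p, self._grads[name]
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def zero_grad(self) -> None:
        for _, _, g in self.named_parameters():
            g[...] = 0.0

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: p for name, p, _ in self.named_parameters()}
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            if p.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.shape} vs {state[name].shape}"
                )
            p[...] = state[name]

    def copy_from(self, other: "Module") -> None:
        """Hard-copy all parameters from an identically shaped module."""
        self.load_state_dict(other.state_dict())


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = self.add_param("W", rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = self.add_param("b", np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self._grads["W"] += self._x.T @ dout
        self._grads["b"] += dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, Hp, Wp, C) padded input -> (N, Ho, Wo, k, k, C) patch tensor."""
    n, hp, wp, c = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = np.empty((n, ho, wo, k, k, c), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[
                :, i : i + stride * ho : stride, j : j + stride * wo : stride, :
            ]
    return cols


class Conv2d(Module):
    """3x3-style convolution via im2col; channel-last layout."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        ksize: int = 3,
        stride: int = 1,
        pad: int = 1,
    ) -> None:
        super().__init__()
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.c_in, self.c_out = c_in, c_out
        fan_in = ksize * ksize * c_in
        self.W = self.add_param(
            "W", rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        )
        self.b = self.add_param("b", np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xshape = x.shape
        self._xpshape = xp.shape
        cols = _im2col(xp, k, s)
        n, ho, wo = cols.shape[:3]
        cols2 = cols.reshape(n * ho * wo, k * k * self.c_in)
        self._cols = cols2
        out = cols2 @ self.W + self.b
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        n, ho, wo, _ = dout.shape
        d2 = dout.reshape(n * ho * wo, self.c_out)
        self._grads["W"] += self._cols.T @ d2
        self._grads["b"] += d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(n, ho, wo, k, k, self.c_in)
        dxp = np.zeros(self._xpshape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[
                    :, :, :, i, j, :
                ]
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class GlobalAvgPool(Module):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Embedding(Module):
    """Token-index lookup table.

    ``forward`` takes an integer array ``(N, T)`` plus a boolean mask of real
    (non-pad) positions; padded positions embed to zero.
    """

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.vocab_size = vocab_size
        self.W = self.add_param("W", rng.normal(0.0, 0.1, size=(vocab_size, dim)))
        self._tokens: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def forward(self, tokens: np.ndarray, mask: np.ndarray) -> np.ndarray:
        self._tokens = tokens
        self._mask = mask
        out = self.W[tokens]
        out[~mask] = 0.0
        return out

    def backward(self, dout: np.ndarray) -> None:
        np.add.at(self._grads["W"], self._tokens[self._mask], dout[self._mask])


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self.add_child(str(i), layer)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
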