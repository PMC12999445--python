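"""Adam optimizer over Module parameter registries."""

from __future__ import annotations

import numpy as np

from .layers import Module


class Adam:
    def __init__(
        self,
        module: Module,
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.module = module
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        for name, p, _ in module.named_parameters():
            self._m[name] = np.zeros_like(p)
            self._v[name] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for name, p, g in self.module.named_parameters():
            m = self._m[name]
            v = self._v[name]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        self.module.zero_grad()
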