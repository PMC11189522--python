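"""Adam optimiser over a Module's parameter tree."""

from __future__ import annotations

import numpy as np

from .layers import F32, Module


class Adam:
    """Adaptive-moment optimiser with bias correction.

    Operates in place on the parameters yielded by ``module.parameters()``;
    state is keyed by qualified parameter name so it survives re-walks of
    the module tree.
    """

    def __init__(
        self,
        module: Module,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = None,
    ):
        self.module = module
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        params = list(self.module.parameters())
        if self.clip_norm is not None:
            total = float(sum(float((g * g).sum()) for _, _, g in params))
            norm = total**0.5
            if norm > self.clip_norm:
                scale = F32(self.clip_norm / (norm + 1e-12))
                for _, _, g in params:
                    g *= scale
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, p, g in params:
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        self.module.zero_grad()
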