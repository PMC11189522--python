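"""Trainable layers in NumPy with explicit forward/backward passes.

Every layer keeps its parameters in ``self.p`` and accumulates gradients in
``self.g`` under matching keys; ``Module.parameters()`` walks the layer tree
so one optimiser can update a whole model.  All math is float32.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

F32 = np.float32

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    from scipy.special import erf

    return (0.5 * x * (1.0 + erf(x / _SQRT2))).astype(F32)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    from scipy.special import erf

    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return (cdf + x * pdf).astype(F32)


class Module:
    """Base class: parameter/gradient bookkeeping over a tree of layers."""

    def __init__(self) -> None:
        self.p: dict[str, np.ndarray] = {}
        self.g: dict[str, np.ndarray] = {}
        self.children: list[tuple[str, "Module"]] = []

    def add_child(self, name: str, mod: "Module") -> "Module":
        self.children.append((name, mod))
        return mod

    def parameters(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (qualified name, parameter, gradient) triples."""
        for k in self.p:
            if k not in self.g:
                self.g[k] = np.zeros_like(self.p[k])
            yield prefix + k, self.p[k], self.g[k]
        for name, child in self.children:
            yield from child.parameters(prefix + name + ".")

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.copy() for k, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {k: p for k, p, _ in self.parameters()}
        if set(own) != set(state):
            raise ValueError("state dict keys do not match model parameters")
        for k, p in own.items():
            if p.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p[...] = state[k]


class Dense(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, init_std: float = 0.02):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.p["W"] = rng.normal(0.0, init_std, (d_in, d_out)).astype(F32)
        self.p["b"] = np.zeros(d_out, dtype=F32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.p["W"] + self.p["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, self.d_in)
        dyf = dy.reshape(-1, self.d_out)
        self.g["W"] += xf.T @ dyf
        self.g["b"] += dyf.sum(axis=0)
        return (dyf @ self.p["W"].T).reshape(x.shape)


class LayerNorm(Module):
    """Normalisation over the last axis with learned scale and shift."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.p["gamma"] = np.ones(d, dtype=F32)
        self.p["beta"] = np.zeros(d, dtype=F32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(F32))
        return self.p["gamma"] * xhat + self.p["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.g["gamma"] += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.g["beta"] += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.p["gamma"]
        # dx = inv * (dxhat - mean(dxhat) - xhat * mean(dxhat * xhat))
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class Dropout(Module):
    """Inverted dropout; identity when rate is 0 or in inference mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        assert rng is not None, "training-mode dropout needs an rng"
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GELU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return gelu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * gelu_grad(self._x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with a key padding mask.

    Padded key positions receive a large negative score before the softmax,
    so no query attends to padding; padded *query* rows still produce
    outputs, which downstream losses and pooling ignore.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.qkv = self.add_child("qkv", Dense(d_model, 3 * d_model, rng))
        self.out = self.add_child("out", Dense(d_model, d_model, rng))

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)

    def forward(self, x: np.ndarray, key_valid: np.ndarray) -> np.ndarray:
        """x: (B,T,D); key_valid: (B,T) boolean, True at real tokens."""
        qkv = self.qkv.forward(x)
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)  # (B,H,T,dh)
        scale = F32(1.0 / math.sqrt(self.d_head))
        s = np.matmul(q, k.transpose(0, 1, 3, 2)) * scale
        s = s + np.where(key_valid[:, None, None, :], F32(0.0), F32(-1e9))
        a = softmax(s, axis=-1).astype(F32)
        o = np.matmul(a, v)
        self._cache = (q, k, v, a, scale)
        return self.out.forward(self._merge(o))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, a, scale = self._cache
        do = self._split(self.out.backward(dy))
        da = np.matmul(do, v.transpose(0, 1, 3, 2))
        dv = np.matmul(a.transpose(0, 1, 3, 2), do)
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds *= scale
        dq = np.matmul(ds, k)
        dk = np.matmul(ds.transpose(0, 1, 3, 2), q)
        dqkv = np.concatenate(
            [self._merge(dq), self._merge(dk), self._merge(dv)], axis=-1
        )
        return self.qkv.backward(dqkv)


def cross_entropy_logits(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean natural-log cross-entropy over rows and its gradient.

    logits: (N, V); targets: (N,) integer class ids.  Returns (loss, dlogits).
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64), axis=-1)
    picked = probs[np.arange(n), targets]
    loss = float(-np.log(np.clip(picked, 1e-300, None)).mean())
    dlogits = probs
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(F32)
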