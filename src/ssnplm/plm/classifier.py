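"""Classification head: attention layers + dense stack + softmax.

The head consumes per-residue encoder states, refines them with
self-attention layers (attention + residual + layer norm), mean-pools over
valid positions, and maps the pooled vector through densely connected GELU
layers to a softmax over the K cluster classes.  With the default widths
(attention width 192, dense stack 384-256-128) on a 512-wide backbone the
head holds ~0.6 M parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn.layers import (
    F32,
    Dense,
    Dropout,
    GELU,
    LayerNorm,
    Module,
    MultiHeadSelfAttention,
    softmax,
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Head hyperparameters; ``hidden_dims`` must list one width per dense
    layer (the softmax output layer to ``n_classes`` is extra)."""

    n_attention_layers: int = 2
    n_dense_layers: int = 3
    n_classes: int = 45
    d_attn: int = 192
    n_heads: int = 4
    hidden_dims: tuple[int, ...] = (384, 256, 128)
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if len(self.hidden_dims) != self.n_dense_layers:
            raise ValueError("hidden_dims must have n_dense_layers entries")
        if min(self.n_attention_layers, self.n_dense_layers, self.n_classes) < 1:
            raise ValueError("layer counts and n_classes must be positive")
        if self.d_attn % self.n_heads != 0:
            raise ValueError("d_attn must be divisible by n_heads")

    def to_dict(self) -> dict:
        return {
            "n_attention_layers": self.n_attention_layers,
            "n_dense_layers": self.n_dense_layers,
            "n_classes": self.n_classes,
            "d_attn": self.d_attn,
            "n_heads": self.n_heads,
            "hidden_dims": list(self.hidden_dims),
            "dropout": self.dropout,
        }


class _AttnLayer(Module):
    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = self.add_child("attn", MultiHeadSelfAttention(cfg.d_attn, cfg.n_heads, rng))
        self.drop = self.add_child("drop", Dropout(cfg.dropout))
        self.ln = self.add_child("ln", LayerNorm(cfg.d_attn))

    def forward(self, x, valid, train, rng):
        return self.ln.forward(x + self.drop.forward(self.attn.forward(x, valid), train, rng))

    def backward(self, dy):
        dx = self.ln.backward(dy)
        return dx + self.attn.backward(self.drop.backward(dx))


class ClassificationHead(Module):
    """Maps (B, T, d_in) per-residue states + validity mask to (B, K) logits."""

    def __init__(self, cfg: ClassifierConfig, d_in: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.d_in = d_in
        self.inproj = self.add_child("inproj", Dense(d_in, cfg.d_attn, rng))
        self.attn_layers = [
            self.add_child(f"attn{i}", _AttnLayer(cfg, rng))
            for i in range(cfg.n_attention_layers)
        ]
        dims = [cfg.d_attn, *cfg.hidden_dims]
        self.dense_layers = []
        self.acts = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.dense_layers.append(self.add_child(f"dense{i}", Dense(a, b, rng)))
            self.acts.append(self.add_child(f"act{i}", GELU()))
        self.out = self.add_child("out", Dense(dims[-1], cfg.n_classes, rng))

    def forward(
        self,
        states: np.ndarray,
        valid: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Return (B, n_classes) logits; ``valid`` is (B, T) boolean."""
        x = self.inproj.forward(states.astype(F32))
        for layer in self.attn_layers:
            x = layer.forward(x, valid, train, rng)
        counts = valid.sum(axis=1, keepdims=True).astype(F32)
        if (counts == 0).any():
            raise ValueError("a sequence has no valid positions to pool over")
        pooled = (x * valid[:, :, None]).sum(axis=1) / counts
        self._pool_cache = (valid, counts, x.shape)
        h = pooled
        for dense, act in zip(self.dense_layers, self.acts):
            h = act.forward(dense.forward(h))
        return self.out.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the input states."""
        dh = self.out.backward(dlogits)
        for dense, act in zip(reversed(self.dense_layers), reversed(self.acts)):
            dh = dense.backward(act.backward(dh))
        valid, counts, shape = self._pool_cache
        dx = np.zeros(shape, dtype=F32)
        dx[valid] = np.repeat(dh / counts, valid.sum(axis=1), axis=0)
        for layer in reversed(self.attn_layers):
            dx = layer.backward(dx)
        return self.inproj.backward(dx)

    def predict_probs(self, states: np.ndarray, valid: np.ndarray) -> np.ndarray:
        """Softmax class probabilities in inference mode."""
        return softmax(self.forward(states, valid, train=False), axis=-1)
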