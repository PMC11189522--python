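"""BERT-style transformer encoder over amino-acid token ids, with an MLM
prediction head, in NumPy.

The encoder is post-layer-norm ("residual then norm", the original BERT
arrangement): each block applies multi-head self-attention and a GELU
feed-forward sublayer, each followed by dropout, a residual connection and
layer normalisation.  Token and learned positional embeddings are summed at
the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    F32,
    Dense,
    Dropout,
    GELU,
    LayerNorm,
    Module,
    MultiHeadSelfAttention,
)


@dataclass(frozen=True)
class EncoderConfig:
    """Backbone hyperparameters.

    The defaults (5 blocks, width 512, 8 heads, feed-forward 2048,
    context 1024) give a backbone of roughly 17 M parameters — a compact
    protein language model an order of magnitude smaller than
    general-purpose pLMs.  Desk-scale tests use far smaller configs.
    """

    n_blocks: int = 5
    d_model: int = 512
    n_heads: int = 8
    d_feedforward: int = 2048
    dropout: float = 0.1
    max_length: int = 1024

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.n_blocks, self.d_model, self.n_heads, self.d_feedforward, self.max_length) < 1:
            raise ValueError("all size fields must be positive")

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "d_model": self.d_model,
            "n_heads": self.n_heads,
            "d_feedforward": self.d_feedforward,
            "dropout": self.dropout,
            "max_length": self.max_length,
        }


class TransformerBlock(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = self.add_child("attn", MultiHeadSelfAttention(cfg.d_model, cfg.n_heads, rng))
        self.ln1 = self.add_child("ln1", LayerNorm(cfg.d_model))
        self.ff1 = self.add_child("ff1", Dense(cfg.d_model, cfg.d_feedforward, rng))
        self.act = self.add_child("act", GELU())
        self.ff2 = self.add_child("ff2", Dense(cfg.d_feedforward, cfg.d_model, rng))
        self.ln2 = self.add_child("ln2", LayerNorm(cfg.d_model))
        self.drop1 = self.add_child("drop1", Dropout(cfg.dropout))
        self.drop2 = self.add_child("drop2", Dropout(cfg.dropout))

    def forward(
        self, x: np.ndarray, key_valid: np.ndarray, train: bool, rng: np.random.Generator | None
    ) -> np.ndarray:
        h = self.ln1.forward(x + self.drop1.forward(self.attn.forward(x, key_valid), train, rng))
        f = self.ff2.forward(self.act.forward(self.ff1.forward(h)))
        return self.ln2.forward(h + self.drop2.forward(f, train, rng))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.ln2.backward(dy)
        df = self.drop2.backward(dh)
        dh = dh + self.ff1.backward(self.act.backward(self.ff2.backward(df)))
        dx = self.ln1.backward(dh)
        return dx + self.attn.backward(self.drop1.backward(dx))


class TransformerEncoder(Module):
    """Token + positional embedding followed by ``n_blocks`` encoder blocks.

    ``forward`` maps int token ids (B, T) to hidden states (B, T, d_model);
    position 0 is reserved for the padding id, whose key positions are
    masked out of every attention softmax.
    """

    def __init__(self, cfg: EncoderConfig, vocab_size: int, pad_id: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.pad_id = pad_id
        self.p["tok_emb"] = rng.normal(0.0, 0.02, (vocab_size, cfg.d_model)).astype(F32)
        self.p["pos_emb"] = rng.normal(0.0, 0.02, (cfg.max_length, cfg.d_model)).astype(F32)
        self.emb_drop = self.add_child("emb_drop", Dropout(cfg.dropout))
        self.blocks = [
            self.add_child(f"block{i}", TransformerBlock(cfg, rng)) for i in range(cfg.n_blocks)
        ]

    def forward(
        self, ids: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if ids.shape[1] > self.cfg.max_length:
            raise ValueError(f"sequence length {ids.shape[1]} exceeds max_length")
        self._ids = ids
        valid = ids != self.pad_id
        x = self.p["tok_emb"][ids] + self.p["pos_emb"][None, : ids.shape[1]]
        x = self.emb_drop.forward(x.astype(F32), train, rng)
        for blk in self.blocks:
            x = blk.forward(x, valid, train, rng)
        return x

    def backward(self, dh: np.ndarray) -> None:
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        dx = self.emb_drop.backward(dh)
        ids = self._ids
        if "tok_emb" not in self.g:
            self.g["tok_emb"] = np.zeros_like(self.p["tok_emb"])
            self.g["pos_emb"] = np.zeros_like(self.p["pos_emb"])
        np.add.at(self.g["tok_emb"], ids.reshape(-1), dx.reshape(-1, dx.shape[-1]))
        self.g["pos_emb"][: ids.shape[1]] += dx.sum(axis=0)

    def block_parameter_count(self) -> int:
        return sum(m.n_parameters() for m in self.blocks)


class MLMHead(Module):
    """Masked-token prediction head: dense + GELU + layer norm + vocab logits."""

    def __init__(self, d_model: int, vocab_size: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc = self.add_child("fc", Dense(d_model, d_model, rng))
        self.act = self.add_child("act", GELU())
        self.ln = self.add_child("ln", LayerNorm(d_model))
        self.out = self.add_child("out", Dense(d_model, vocab_size, rng))

    def forward(self, states: np.ndarray) -> np.ndarray:
        return self.out.forward(self.ln.forward(self.act.forward(self.fc.forward(states))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc.backward(self.act.backward(self.ln.backward(self.out.backward(dy))))
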