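"""Amino-acid tokenizer and BERT-style masking for MLM pre-training."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..seqio import STANDARD_AA, ProteinSequence

logger = logging.getLogger(__name__)

RESIDUE_ALPHABET = STANDARD_AA + "X"  # 21 letters


@dataclass(frozen=True)
class Tokenizer:
    """Fixed vocabulary: PAD=0, then MASK, CLS, EOS, UNK, then the 21
    residue symbols.  ``max_length`` bounds the *token* length including
    the CLS/EOS delimiters."""

    max_length: int = 1024
    vocab: dict[str, int] = field(default_factory=dict)

    PAD, MASK, CLS, EOS, UNK = 0, 1, 2, 3, 4
    _N_SPECIALS = 5

    def __post_init__(self) -> None:
        if self.max_length < 3:
            raise ValueError("max_length must allow CLS + one residue + EOS")
        if not self.vocab:
            v = {"<pad>": 0, "<mask>": 1, "<cls>": 2, "<eos>": 3, "<unk>": 4}
            for i, aa in enumerate(RESIDUE_ALPHABET):
                v[aa] = self._N_SPECIALS + i
            object.__setattr__(self, "vocab", v)

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)  # 26

    @property
    def first_residue_id(self) -> int:
        return self._N_SPECIALS

    def is_residue_id(self, ids: np.ndarray) -> np.ndarray:
        return ids >= self.first_residue_id

    def id_to_symbol(self, i: int) -> str:
        for sym, j in self.vocab.items():
            if j == i:
                return sym
        raise KeyError(i)


def tokenize(seq: ProteinSequence, tok: Tokenizer) -> np.ndarray:
    """``[CLS] residues [EOS]``, truncated to ``max_length`` with the
    delimiters kept (a warning is logged on truncation)."""
    body = [tok.vocab.get(c, tok.UNK) for c in seq.residues]
    room = tok.max_length - 2
    if len(body) > room:
        logger.warning("sequence %s truncated from %d to %d residues",
                       seq.id, len(body), room)
        body = body[:room]
    return np.array([tok.CLS, *body, tok.EOS], dtype=np.int64)


def detokenize(ids: np.ndarray, tok: Tokenizer) -> str:
    """Inverse of :func:`tokenize` for untruncated sequences."""
    out = []
    for i in ids:
        i = int(i)
        if i in (tok.CLS, tok.EOS, tok.PAD):
            continue
        out.append(tok.id_to_symbol(i))
    return "".join(out)


def pad_batch(token_lists: list[np.ndarray], pad_id: int = 0) -> np.ndarray:
    """Stack variable-length token lists into a (B, T_max) int array."""
    t = max(len(x) for x in token_lists)
    out = np.full((len(token_lists), t), pad_id, dtype=np.int64)
    for i, x in enumerate(token_lists):
        out[i, : len(x)] = x
    return out


def mask_for_mlm(
    ids: np.ndarray,
    rate: float = 0.15,
    rng: np.random.Generator | None = None,
    scheme: tuple[float, float, float] = (0.8, 0.1, 0.1),
    tok: Tokenizer | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BERT corruption of a (B, T) or (T,) id array.

    Each residue position (specials and padding are never touched) is
    independently selected with probability ``rate``; selected positions
    become MASK / a uniform-random residue / stay unchanged with the
    ``scheme`` proportions (default 80/10/10).  Returns
    ``(corrupted ids, selected positions as an index tuple, original ids
    at those positions)`` — the MLM loss is computed at the selected
    positions only.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("mask rate must be in [0, 1]")
    if abs(sum(scheme) - 1.0) > 1e-9 or min(scheme) < 0:
        raise ValueError("scheme must be three nonnegative fractions summing to 1")
    tok = tok or Tokenizer()
    rng = rng or np.random.default_rng()
    squeeze = ids.ndim == 1
    ids2 = ids[None, :] if squeeze else ids
    eligible = tok.is_residue_id(ids2)
    if not eligible.any():
        raise ValueError("no non-special tokens to mask")
    selected = eligible & (rng.random(ids2.shape) < rate)
    corrupted = ids2.copy()
    pos = np.nonzero(selected)
    targets = ids2[pos].copy()
    u = rng.random(len(targets))
    to_mask = u < scheme[0]
    to_rand = (u >= scheme[0]) & (u < scheme[0] + scheme[1])
    corrupted[pos[0][to_mask], pos[1][to_mask]] = tok.MASK
    n_rand = int(to_rand.sum())
    if n_rand:
        rand_ids = rng.integers(tok.first_residue_id, tok.vocab_size, size=n_rand)
        corrupted[pos[0][to_rand], pos[1][to_rand]] = rand_ids
    if squeeze:
        return corrupted[0], pos[1], targets
    return corrupted, pos, targets
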