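"""Single-file model checkpoints.

A checkpoint is one ``.npz`` archive holding every parameter array plus a
JSON metadata entry with the encoder/classifier configurations and the
tokenizer vocabulary, so a model can be reloaded without any side files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..nn.encoder import EncoderConfig, MLMHead, TransformerEncoder
from .classifier import ClassificationHead, ClassifierConfig
from .tokenizer import Tokenizer


def save_checkpoint(
    path: str | Path,
    encoder: TransformerEncoder,
    tokenizer: Tokenizer,
    head: ClassificationHead | None = None,
    mlm_head: MLMHead | None = None,
) -> None:
    meta = {
        "encoder": encoder.cfg.to_dict(),
        "vocab": tokenizer.vocab,
        "max_length": tokenizer.max_length,
        "classifier": head.cfg.to_dict() if head is not None else None,
        "head_d_in": head.d_in if head is not None else None,
        "has_mlm_head": mlm_head is not None,
    }
    arrays = {"enc/" + k: p for k, p, _ in encoder.parameters()}
    if head is not None:
        arrays.update({"head/" + k: p for k, p, _ in head.parameters()})
    if mlm_head is not None:
        arrays.update({"mlm/" + k: p for k, p, _ in mlm_head.parameters()})
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(
    path: str | Path,
) -> tuple[TransformerEncoder, Tokenizer, ClassificationHead | None, MLMHead | None]:
    with np.load(path) as data:
        meta = json.loads(data["__meta__"].tobytes().decode())
        enc_cfg = EncoderConfig(**meta["encoder"])
        tok = Tokenizer(max_length=meta["max_length"], vocab=meta["vocab"])
        encoder = TransformerEncoder(enc_cfg, tok.vocab_size, tok.PAD)
        encoder.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("enc/")}
        )
        head = None
        if meta["classifier"] is not None:
            cfg = meta["classifier"]
            cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
            head = ClassificationHead(ClassifierConfig(**cfg), d_in=meta["head_d_in"])
            head.load_state_dict(
                {k[5:]: data[k] for k in data.files if k.startswith("head/")}
            )
        mlm = None
        if meta.get("has_mlm_head"):
            mlm = MLMHead(enc_cfg.d_model, tok.vocab_size)
            mlm.load_state_dict(
                {k[4:]: data[k] for k in data.files if k.startswith("mlm/")}
            )
    return encoder, tok, head, mlm
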