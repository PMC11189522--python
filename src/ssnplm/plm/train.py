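"""Two-phase semi-supervised training and the one-hot baseline.

Phase 1 (:func:`pretrain_mlm`) trains the transformer encoder with masked
language modelling on an unlabelled corpus under a 95/5 train/validation
split.  Phase 2 (:func:`train_classifier`) trains the attention + dense
head on the labelled subset under a stratified 80/20 split, with the
backbone frozen by default; when frozen, encoder states are computed once
and cached, which makes head training cheap.  :func:`one_hot_baseline`
trains the identical head architecture on raw one-hot encodings instead of
learned representations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..nn.encoder import EncoderConfig, MLMHead, TransformerEncoder
from ..nn.layers import F32, cross_entropy_logits
from ..nn.optim import Adam
from ..seqio import ProteinSequence, SequenceSet
from .classifier import ClassificationHead, ClassifierConfig
from .metrics import EvalReport, Prediction, accuracy, ece_perplexity
from .splits import SplitSpec, split_indices, stratified_split_indices
from .tokenizer import RESIDUE_ALPHABET, Tokenizer, mask_for_mlm, pad_batch, tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimSettings:
    """Optimisation knobs (never baked into the operations)."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-4
    mask_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid optimisation settings")


def _encode_corpus(seqs: SequenceSet, tok: Tokenizer) -> list[np.ndarray]:
    return [tokenize(s, tok) for s in seqs]


def _mlm_loss_and_backward(
    encoder: TransformerEncoder,
    head: MLMHead,
    batch: np.ndarray,
    tok: Tokenizer,
    rng: np.random.Generator | None,
    mask_rate: float,
    train: bool,
) -> float:
    """Masked-position cross-entropy; runs backward when ``train``."""
    corrupted, pos, targets = mask_for_mlm(batch, mask_rate, rng, tok=tok)
    if len(targets) == 0:
        return float("nan")
    h = encoder.forward(corrupted, train=train, rng=rng)
    states = h[pos]
    logits = head.forward(states)
    loss, dlogits = cross_entropy_logits(logits, targets)
    if train:
        dstates = head.backward(dlogits)
        dh = np.zeros_like(h)
        dh[pos] = dstates
        encoder.backward(dh)
    return loss


def pretrain_mlm(
    seqs: SequenceSet,
    enc: EncoderConfig | None = None,
    split: SplitSpec | None = None,
    settings: OptimSettings | None = None,
    seed: int = 0,
) -> tuple[TransformerEncoder, MLMHead, Tokenizer, list[dict]]:
    """Masked-language-model pre-training.

    Masking is re-drawn every epoch for the training side (dynamic masking);
    the validation corruption is drawn once from a fixed stream so the
    per-epoch validation losses are comparable.  Returns the trained
    encoder, the MLM head, the tokenizer, and a per-epoch loss history
    ``[{"epoch": e, "train_loss": ..., "val_loss": ...}, ...]``.
    """
    enc = enc or EncoderConfig()
    split = split or SplitSpec(train_fraction=0.95, seed=seed)
    settings = settings or OptimSettings()
    if len(seqs) < 20:
        raise ValueError("pre-training needs at least 20 sequences")

    tok = Tokenizer(max_length=enc.max_length)
    tokens = _encode_corpus(seqs, tok)
    train_idx, val_idx = split_indices(len(tokens), split)
    logger.info("MLM pre-training: %d train / %d validation sequences",
                len(train_idx), len(val_idx))

    encoder = TransformerEncoder(enc, tok.vocab_size, tok.PAD, seed=seed)
    head = MLMHead(enc.d_model, tok.vocab_size, seed=seed + 1)
    root = _Composite(encoder, head)
    opt = Adam(root, lr=settings.learning_rate)
    rng = np.random.default_rng(seed + 2)

    # fixed validation corruption: one batch set, one mask draw
    val_rng = np.random.default_rng(seed + 3)
    val_batches = [
        pad_batch([tokens[i] for i in val_idx[o : o + settings.batch_size]], tok.PAD)
        for o in range(0, len(val_idx), settings.batch_size)
    ]
    val_masks = [
        mask_for_mlm(b, settings.mask_rate, val_rng, tok=tok) for b in val_batches
    ]

    history: list[dict] = []
    for epoch in range(1, settings.epochs + 1):
        order = rng.permutation(len(train_idx))
        losses, weights = [], []
        for o in range(0, len(order), settings.batch_size):
            chunk = [tokens[train_idx[i]] for i in order[o : o + settings.batch_size]]
            batch = pad_batch(chunk, tok.PAD)
            opt.zero_grad()
            loss = _mlm_loss_and_backward(
                encoder, head, batch, tok, rng, settings.mask_rate, train=True
            )
            opt.step()
            losses.append(loss)
            weights.append(len(chunk))
        train_loss = float(np.average(losses, weights=weights))
        val_losses = []
        for (corrupted, pos, targets) in val_masks:
            h = encoder.forward(corrupted, train=False)
            logits = head.forward(h[pos])
            loss, _ = cross_entropy_logits(logits, targets)
            val_losses.append((loss, len(targets)))
        val_loss = float(
            np.average([l for l, _ in val_losses], weights=[w for _, w in val_losses])
        )
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d: train MLM loss %.4f, val %.4f", epoch, train_loss, val_loss)
    return encoder, head, tok, history


class _Composite:
    """Optimise several modules as one parameter tree."""

    def __init__(self, *modules):
        self.modules = modules

    def parameters(self):
        for i, m in enumerate(self.modules):
            yield from m.parameters(prefix=f"m{i}.")

    def zero_grad(self):
        for m in self.modules:
            m.zero_grad()


def _batched_states(
    encoder: TransformerEncoder, tokens: list[np.ndarray], tok: Tokenizer, batch_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode per-residue states, padded to the corpus max length.

    Returns ``(states (n, T, d), residue_valid (n, T))`` where validity
    marks residue positions only (CLS/EOS/PAD excluded) — the positions
    pooling and embedding aggregate over.
    """
    t_max = max(len(t) for t in tokens)
    n = len(tokens)
    states = np.zeros((n, t_max, encoder.cfg.d_model), dtype=F32)
    valid = np.zeros((n, t_max), dtype=bool)
    for o in range(0, n, batch_size):
        chunk = tokens[o : o + batch_size]
        batch = pad_batch(chunk, tok.PAD)
        h = encoder.forward(batch, train=False)
        states[o : o + len(chunk), : batch.shape[1]] = h
        valid[o : o + len(chunk), : batch.shape[1]] = tok.is_residue_id(batch)
    return states, valid


def embed(
    encoder: TransformerEncoder,
    seqs: SequenceSet,
    tok: Tokenizer | None = None,
    batch_size: int = 32,
) -> np.ndarray:
    """Per-sequence representations: final-block hidden states mean-pooled
    over residue positions.  Deterministic in inference mode; identical
    sequences give identical rows."""
    tok = tok or Tokenizer(max_length=encoder.cfg.max_length)
    tokens = _encode_corpus(seqs, tok)
    states, valid = _batched_states(encoder, tokens, tok, batch_size)
    counts = valid.sum(axis=1, keepdims=True)
    return (states * valid[:, :, None]).sum(axis=1) / counts


def build_classifier(cfg: ClassifierConfig, d_model: int, seed: int = 0) -> ClassificationHead:
    """Construct the task head for a backbone of width ``d_model``."""
    head = ClassificationHead(cfg, d_in=d_model, seed=seed)
    logger.info("classification head: %d parameters", head.n_parameters())
    return head


def _resolve_labels(corpus_or_labels, seqs: SequenceSet | None):
    """Accept a LabelledCorpus or (SequenceSet, ClusterLabelSet/dict)."""
    if seqs is None:
        sequences = corpus_or_labels.sequences
        mapping = corpus_or_labels.truth
    else:
        sequences = seqs
        mapping = getattr(corpus_or_labels, "labels", corpus_or_labels)
    labelled = [s for s in sequences if s.id in mapping]
    return labelled, {s.id: mapping[s.id] for s in labelled}


def _train_head_on_states(
    head: ClassificationHead,
    states: np.ndarray,
    valid: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    settings: OptimSettings,
    seed: int,
) -> None:
    opt = Adam(head, lr=settings.learning_rate)
    rng = np.random.default_rng(seed)
    for epoch in range(settings.epochs):
        order = rng.permutation(len(train_idx))
        for o in range(0, len(order), settings.batch_size):
            sel = train_idx[order[o : o + settings.batch_size]]
            opt.zero_grad()
            logits = head.forward(states[sel], valid[sel], train=True, rng=rng)
            loss, dlogits = cross_entropy_logits(logits, y[sel])
            head.backward(dlogits)
            opt.step()


def _predictions_from_states(
    head: ClassificationHead,
    ids: list[str],
    states: np.ndarray,
    valid: np.ndarray,
    idx: np.ndarray,
    batch_size: int,
) -> list[Prediction]:
    preds = []
    for o in range(0, len(idx), batch_size):
        sel = idx[o : o + batch_size]
        probs = head.predict_probs(states[sel], valid[sel])
        preds.extend(
            Prediction.from_probabilities(ids[i], p) for i, p in zip(sel, probs)
        )
    return preds


#: head-training defaults: small datasets need more steps at a higher rate
#: than backbone pre-training before the softmax sharpens
HEAD_LR_DEFAULT = 3e-3
HEAD_EPOCHS_DEFAULT = 60


def classifier_split_ids(
    corpus_or_labels,
    seqs: SequenceSet | None = None,
    split: SplitSpec | None = None,
) -> tuple[list[str], list[str]]:
    """The (train ids, test ids) a classifier run with this split uses;
    mirrors the internal ordering so callers can audit the held-out set."""
    split = split or SplitSpec(train_fraction=0.80, seed=0)
    labelled, mapping = _resolve_labels(corpus_or_labels, seqs)
    y0 = np.array([mapping[s.id] for s in labelled]) - 1
    tr, te = stratified_split_indices(y0, split)
    ids = [s.id for s in labelled]
    return [ids[i] for i in tr], [ids[i] for i in te]


def train_classifier(
    encoder: TransformerEncoder,
    head: ClassificationHead,
    corpus_or_labels,
    seqs: SequenceSet | None = None,
    split: SplitSpec | None = None,
    freeze_backbone: bool = True,
    settings: OptimSettings | None = None,
    tok: Tokenizer | None = None,
    seed: int = 0,
) -> tuple[ClassificationHead, EvalReport]:
    """Supervised task-training on the labelled subset.

    ``corpus_or_labels`` is either a LabelledCorpus or a ClusterLabelSet /
    id->label dict paired with ``seqs``.  The split is stratified by label
    (80/20 by default).  With the backbone frozen (default) the encoder is
    run once in inference mode and only the head is optimised; with
    ``freeze_backbone=False`` gradients flow into the encoder as well.
    Returns the trained head and an :class:`EvalReport` on the held-out
    test side.
    """
    split = split or SplitSpec(train_fraction=0.80, seed=seed)
    settings = settings or OptimSettings(epochs=HEAD_EPOCHS_DEFAULT, learning_rate=HEAD_LR_DEFAULT)
    tok = tok or Tokenizer(max_length=encoder.cfg.max_length)
    labelled, mapping = _resolve_labels(corpus_or_labels, seqs)
    if not labelled:
        raise ValueError("no labelled sequences")
    n_classes = head.cfg.n_classes
    y = np.array([mapping[s.id] for s in labelled])
    if (y < 1).any() or (y > n_classes).any():
        raise ValueError(f"labels must lie in 1..{n_classes}")
    y0 = y - 1
    ids = [s.id for s in labelled]
    tokens = [tokenize(s, tok) for s in labelled]
    train_idx, test_idx = stratified_split_indices(y0, split)
    logger.info("task-training: %d train / %d test sequences", len(train_idx), len(test_idx))

    if freeze_backbone:
        before = _checksum(encoder)
        states, valid = _batched_states(encoder, tokens, tok, settings.batch_size)
        _train_head_on_states(head, states, valid, y0, train_idx, settings, seed + 11)
        assert _checksum(encoder) == before, "frozen backbone must not change"
    else:
        _train_joint(encoder, head, tokens, tok, y0, train_idx, settings, seed + 11)
        states, valid = _batched_states(encoder, tokens, tok, settings.batch_size)

    preds = _predictions_from_states(head, ids, states, valid, test_idx, settings.batch_size)
    test_labels = {ids[i]: int(y[i]) for i in test_idx}
    report = EvalReport(len(preds), accuracy(preds, test_labels), ece_perplexity(preds, test_labels))
    logger.info("held-out report: %s", report)
    return head, report


def _train_joint(encoder, head, tokens, tok, y0, train_idx, settings, seed):
    root = _Composite(encoder, head)
    opt = Adam(root, lr=settings.learning_rate)
    rng = np.random.default_rng(seed)
    for epoch in range(settings.epochs):
        order = rng.permutation(len(train_idx))
        for o in range(0, len(order), settings.batch_size):
            sel = train_idx[order[o : o + settings.batch_size]]
            batch = pad_batch([tokens[i] for i in sel], tok.PAD)
            opt.zero_grad()
            h = encoder.forward(batch, train=True, rng=rng)
            valid = tok.is_residue_id(batch)
            logits = head.forward(h, valid, train=True, rng=rng)
            loss, dlogits = cross_entropy_logits(logits, y0[sel])
            dstates = head.backward(dlogits)
            encoder.backward(dstates)
            opt.step()


def _checksum(module) -> float:
    return float(sum(float(np.abs(p).sum()) for _, p, _ in module.parameters()))


def predict(
    encoder: TransformerEncoder,
    head: ClassificationHead,
    seqs: SequenceSet,
    tok: Tokenizer | None = None,
    batch_size: int = 32,
) -> list[Prediction]:
    """One Prediction per sequence, deterministic in inference mode."""
    tok = tok or Tokenizer(max_length=encoder.cfg.max_length)
    tokens = _encode_corpus(seqs, tok)
    states, valid = _batched_states(encoder, tokens, tok, batch_size)
    return _predictions_from_states(
        head, seqs.ids, states, valid, np.arange(len(tokens)), batch_size
    )


def one_hot_encode(seq: ProteinSequence, max_length: int) -> np.ndarray:
    """(max_length, 21) one-hot rows over the residue alphabet; all-zero
    rows beyond the sequence end.  Sequences longer than ``max_length``
    are truncated."""
    out = np.zeros((max_length, len(RESIDUE_ALPHABET)), dtype=F32)
    for i, c in enumerate(seq.residues[:max_length]):
        out[i, RESIDUE_ALPHABET.index(c)] = 1.0
    return out


def one_hot_baseline(
    corpus_or_labels,
    seqs: SequenceSet | None = None,
    max_length: int = 1024,
    head_cfg: ClassifierConfig | None = None,
    split: SplitSpec | None = None,
    settings: OptimSettings | None = None,
    seed: int = 0,
) -> tuple[ClassificationHead, EvalReport]:
    """The identical task-head architecture trained on raw one-hot
    encodings of the sequences (no learned representations)."""
    head_cfg = head_cfg or ClassifierConfig()
    split = split or SplitSpec(train_fraction=0.80, seed=seed)
    settings = settings or OptimSettings(epochs=HEAD_EPOCHS_DEFAULT, learning_rate=HEAD_LR_DEFAULT)
    labelled, mapping = _resolve_labels(corpus_or_labels, seqs)
    if not labelled:
        raise ValueError("no labelled sequences")
    y = np.array([mapping[s.id] for s in labelled])
    if (y < 1).any() or (y > head_cfg.n_classes).any():
        raise ValueError(f"labels must lie in 1..{head_cfg.n_classes}")
    y0 = y - 1
    ids = [s.id for s in labelled]
    t_used = min(max_length, max(len(s) for s in labelled))
    states = np.stack([one_hot_encode(s, t_used) for s in labelled])
    valid = states.sum(axis=2) > 0
    head = ClassificationHead(head_cfg, d_in=states.shape[2], seed=seed)
    train_idx, test_idx = stratified_split_indices(y0, split)
    _train_head_on_states(head, states, valid, y0, train_idx, settings, seed + 11)
    preds = _predictions_from_states(head, ids, states, valid, test_idx, settings.batch_size)
    test_labels = {ids[i]: int(y[i]) for i in test_idx}
    report = EvalReport(len(preds), accuracy(preds, test_labels), ece_perplexity(preds, test_labels))
    logger.info("one-hot baseline report: %s", report)
    return head, report
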