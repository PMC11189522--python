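"""Training behaviour at desk scale: MLM memorisation, determinism,
split proportions, frozen backbone, degenerate labels, prediction
contracts, one-hot encoding rules."""

import numpy as np
import pytest

from ssnplm import FamilyConfig, ProteinSequence, SequenceSet, generate_families
from ssnplm.nn import EncoderConfig
from ssnplm.plm import (
    ClassifierConfig,
    SplitSpec,
    one_hot_encode,
    predict,
    pretrain_mlm,
    train_classifier,
)
from ssnplm.plm.train import OptimSettings, build_classifier

from conftest import random_protein

TINY = EncoderConfig(n_blocks=2, d_model=32, n_heads=2, d_feedforward=64,
                     dropout=0.0, max_length=48)
FAST = OptimSettings(epochs=2, batch_size=16, learning_rate=1e-3)


def repeated_corpus(rng, n=100, length=30):
    base = random_protein(rng, length, "base")
    return SequenceSet(
        [ProteinSequence(f"s{i}", base.residues) for i in range(n)]
    )


class TestPretrainMLM:
    def test_memorises_a_repeated_sequence(self, rng):
        """On a corpus of one repeated sequence the validation MLM loss
        falls well below its starting value within 30 epochs."""
        seqs = repeated_corpus(rng)
        _, _, _, hist = pretrain_mlm(
            seqs, TINY, settings=OptimSettings(epochs=30, batch_size=16,
                                               learning_rate=1e-3), seed=0
        )
        assert hist[-1]["val_loss"] < 0.5 * hist[0]["val_loss"]

    def test_95_5_split_proportions(self, rng):
        seqs = SequenceSet([random_protein(rng, 20, f"s{i}") for i in range(100)])
        from ssnplm.plm import split_indices

        tr, te = split_indices(len(seqs), SplitSpec(0.95, seed=0))
        assert len(tr) == 95 and len(te) == 5

    def test_fixed_seed_reproduces_epoch_losses(self, rng):
        seqs = SequenceSet([random_protein(rng, 20, f"s{i}") for i in range(24)])
        h1 = pretrain_mlm(seqs, TINY, settings=FAST, seed=7)[3]
        h2 = pretrain_mlm(seqs, TINY, settings=FAST, seed=7)[3]
        assert h1[0]["train_loss"] == h2[0]["train_loss"]
        assert h1 == h2

    def test_too_small_corpus_rejected(self, rng):
        seqs = SequenceSet([random_protein(rng, 20, f"s{i}") for i in range(5)])
        with pytest.raises(ValueError, match="at least 20"):
            pretrain_mlm(seqs, TINY, settings=FAST)


@pytest.fixture(scope="module")
def small_trained():
    """A tiny pretrained encoder + trained head on a 4-family corpus,
    shared across prediction-contract tests."""
    corpus = generate_families(FamilyConfig(4, 12, 40, 0.1, seed=21))
    enc_cfg = EncoderConfig(n_blocks=2, d_model=32, n_heads=2, d_feedforward=64,
                            dropout=0.0, max_length=48)
    encoder, _, tok, _ = pretrain_mlm(
        corpus.sequences, enc_cfg,
        settings=OptimSettings(epochs=5, batch_size=16, learning_rate=1e-3), seed=22
    )
    head_cfg = ClassifierConfig(n_classes=4, d_attn=32, n_heads=2, hidden_dims=(32, 24, 16))
    head = build_classifier(head_cfg, 32, seed=23)
    head, report = train_classifier(
        encoder, head, corpus, split=SplitSpec(0.80, seed=24),
        settings=OptimSettings(epochs=50, batch_size=16, learning_rate=3e-3),
        tok=tok, seed=24,
    )
    return corpus, encoder, head, tok, report


class TestTrainClassifier:
    def test_80_20_split_sizes(self, small_trained):
        _, _, _, _, report = small_trained
        assert report.n == 10  # 20% of 48 labelled sequences (floor convention)

    def test_frozen_backbone_parameters_unchanged(self, rng):
        corpus = generate_families(FamilyConfig(3, 8, 30, 0.1, seed=31))
        encoder, _, tok, _ = pretrain_mlm(
            corpus.sequences, TINY, settings=FAST, seed=32
        )
        before = {k: p.copy() for k, p, _ in encoder.parameters()}
        head = build_classifier(
            ClassifierConfig(n_classes=3, d_attn=16, n_heads=2, hidden_dims=(16, 12, 8)),
            32, seed=33,
        )
        train_classifier(encoder, head, corpus, settings=FAST, tok=tok, seed=33)
        for k, p, _ in encoder.parameters():
            np.testing.assert_array_equal(p, before[k])

    def test_unfrozen_backbone_parameters_do_change(self, rng):
        corpus = generate_families(FamilyConfig(3, 8, 30, 0.1, seed=41))
        encoder, _, tok, _ = pretrain_mlm(
            corpus.sequences, TINY, settings=FAST, seed=42
        )
        before = {k: p.copy() for k, p, _ in encoder.parameters()}
        head = build_classifier(
            ClassifierConfig(n_classes=3, d_attn=16, n_heads=2, hidden_dims=(16, 12, 8)),
            32, seed=43,
        )
        train_classifier(encoder, head, corpus, freeze_backbone=False,
                         settings=FAST, tok=tok, seed=43)
        changed = any(
            not np.array_equal(p, before[k]) for k, p, _ in encoder.parameters()
        )
        assert changed

    def test_single_class_labels_give_perfect_accuracy_and_low_ece(self, rng):
        seqs = SequenceSet([random_protein(rng, 30, f"s{i}") for i in range(30)])
        labels = {s.id: 1 for s in seqs}
        encoder, _, tok, _ = pretrain_mlm(seqs, TINY, settings=FAST, seed=52)
        head = build_classifier(
            ClassifierConfig(n_classes=1, d_attn=16, n_heads=2, hidden_dims=(8, 8, 8)),
            32, seed=53,
        )
        _, report = train_classifier(
            encoder, head, labels, seqs=seqs,
            settings=OptimSettings(epochs=10, batch_size=16, learning_rate=3e-3),
            tok=tok, seed=53,
        )
        assert report.accuracy == 1.0
        assert report.ece == pytest.approx(1.0, abs=0.05)

    def test_out_of_range_label_rejected(self, rng):
        seqs = SequenceSet([random_protein(rng, 30, f"s{i}") for i in range(25)])
        labels = {s.id: 9 for s in seqs}
        encoder, _, tok, _ = pretrain_mlm(seqs, TINY, settings=FAST, seed=62)
        head = build_classifier(
            ClassifierConfig(n_classes=3, d_attn=16, n_heads=2, hidden_dims=(8, 8, 8)),
            32, seed=63,
        )
        with pytest.raises(ValueError, match="labels must lie"):
            train_classifier(encoder, head, labels, seqs=seqs, settings=FAST,
                             tok=tok, seed=63)


class TestPredict:
    def test_probabilities_normalised_and_argmax_consistent(self, small_trained):
        corpus, encoder, head, tok, _ = small_trained
        preds = predict(encoder, head, corpus.sequences, tok)
        assert len(preds) == len(corpus.sequences)
        for p in preds:
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert p.predicted_cluster == int(np.argmax(p.probabilities)) + 1

    def test_majority_of_each_family_predicted_as_itself(self, small_trained):
        corpus, encoder, head, tok, report = small_trained
        assert report.accuracy >= 0.8
        preds = {p.id: p.predicted_cluster for p in
                 predict(encoder, head, corpus.sequences, tok)}
        for fam in (1, 2, 3, 4):
            members = [sid for sid, f in corpus.truth.items() if f == fam]
            hits = sum(preds[sid] == fam for sid in members)
            assert hits > len(members) / 2

    def test_inference_is_deterministic(self, small_trained):
        corpus, encoder, head, tok, _ = small_trained
        p1 = predict(encoder, head, corpus.sequences, tok)
        p2 = predict(encoder, head, corpus.sequences, tok)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.probabilities, b.probabilities)


class TestOneHotEncoding:
    def test_rows_beyond_sequence_end_are_zero(self):
        m = one_hot_encode(ProteinSequence("s", "AC"), max_length=4)
        assert m.shape == (4, 21)
        assert m[0].sum() == 1 and m[1].sum() == 1
        assert m[2:].sum() == 0

    def test_each_residue_row_is_one_hot(self, rng):
        seq = random_protein(rng, 25, "s")
        m = one_hot_encode(seq, max_length=30)
        np.testing.assert_array_equal(m[:25].sum(axis=1), np.ones(25))
        assert set(np.unique(m)) <= {0.0, 1.0}
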