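"""Encoder/head mechanics: gradients vs finite differences, shape and
determinism contracts, parameter-count scaling, splits, checkpoints."""

import numpy as np
import pytest

from ssnplm import ProteinSequence, SequenceSet
from ssnplm.nn import Adam, EncoderConfig, MLMHead, TransformerEncoder
from ssnplm.nn.layers import cross_entropy_logits
from ssnplm.plm import (
    ClassifierConfig,
    ClassificationHead,
    SplitSpec,
    Tokenizer,
    embed,
    load_checkpoint,
    mask_for_mlm,
    save_checkpoint,
    split_indices,
    stratified_split_indices,
    tokenize,
)

from conftest import random_protein

TINY = EncoderConfig(n_blocks=2, d_model=16, n_heads=2, d_feedforward=32,
                     dropout=0.0, max_length=32)


def tiny_encoder(seed=0):
    tok = Tokenizer(max_length=32)
    return TransformerEncoder(TINY, tok.vocab_size, tok.PAD, seed=seed), tok


class TestGradients:
    def test_encoder_and_mlm_head_match_finite_differences(self):
        """Analytic backprop through embedding, attention, layer norm and
        feed-forward agrees with central finite differences."""
        enc, tok = tiny_encoder()
        head = MLMHead(16, tok.vocab_size, seed=1)
        ids = np.array([[2, 5, 6, 7, 8, 9, 3, 0, 0], [2, 10, 11, 12, 3, 0, 0, 0, 0]])
        corrupted, pos, targets = mask_for_mlm(ids, 0.5, np.random.default_rng(7), tok=tok)

        def loss():
            h = enc.forward(corrupted)
            return cross_entropy_logits(head.forward(h[pos]), targets)[0]

        enc.zero_grad(), head.zero_grad()
        h = enc.forward(corrupted)
        l, dl = cross_entropy_logits(head.forward(h[pos]), targets)
        dh = np.zeros_like(h)
        dh[pos] = head.backward(dl)
        enc.backward(dh)

        check_rng = np.random.default_rng(3)
        for name, p, g in list(enc.parameters()) + list(head.parameters()):
            for flat in check_rng.choice(p.size, size=min(2, p.size), replace=False):
                ix = np.unravel_index(flat, p.shape)
                eps, old = 1e-3, p[ix]
                p[ix] = old + eps
                l1 = loss()
                p[ix] = old - eps
                l2 = loss()
                p[ix] = old
                num = (l1 - l2) / (2 * eps)
                assert num == pytest.approx(g[ix], abs=2e-2, rel=2e-2), name

    def test_classification_head_matches_finite_differences(self):
        cfg = ClassifierConfig(n_attention_layers=2, n_dense_layers=3, n_classes=5,
                               d_attn=12, n_heads=2, hidden_dims=(16, 12, 8), dropout=0.0)
        head = ClassificationHead(cfg, d_in=10, seed=0)
        rng = np.random.default_rng(1)
        states = rng.normal(size=(3, 7, 10)).astype(np.float32)
        valid = np.ones((3, 7), bool)
        valid[0, 5:] = False
        y = np.array([0, 2, 4])

        def loss():
            return cross_entropy_logits(head.forward(states, valid), y)[0]

        head.zero_grad()
        l, dl = cross_entropy_logits(head.forward(states, valid), y)
        head.backward(dl)
        check_rng = np.random.default_rng(2)
        for name, p, g in head.parameters():
            for flat in check_rng.choice(p.size, size=min(2, p.size), replace=False):
                ix = np.unravel_index(flat, p.shape)
                eps, old = 1e-3, p[ix]
                p[ix] = old + eps
                l1 = loss()
                p[ix] = old - eps
                l2 = loss()
                p[ix] = old
                assert (l1 - l2) / (2 * eps) == pytest.approx(g[ix], abs=2e-2, rel=2e-2), name


class TestEmbed:
    def test_shape_identity_and_permutation(self, rng):
        enc, tok = tiny_encoder()
        seqs = [random_protein(rng, 12, f"s{i}") for i in range(5)]
        seqs.append(ProteinSequence("dup", seqs[0].residues))
        m = embed(enc, SequenceSet(seqs), tok)
        assert m.shape == (6, 16)
        np.testing.assert_allclose(m[0], m[5], atol=1e-5)
        perm = [3, 1, 4, 0, 2, 5]
        m2 = embed(enc, SequenceSet([seqs[i] for i in perm]), tok)
        np.testing.assert_allclose(m2, m[perm], atol=1e-5)


class TestParameterCounts:
    def test_default_head_near_point_six_million(self):
        head = ClassificationHead(ClassifierConfig(), d_in=512, seed=0)
        assert head.n_parameters() == pytest.approx(0.6e6, rel=0.20)

    def test_head_output_width_is_n_classes(self):
        head = ClassificationHead(ClassifierConfig(), d_in=512, seed=0)
        states = np.zeros((2, 5, 512), dtype=np.float32)
        valid = np.ones((2, 5), bool)
        probs = head.predict_probs(states, valid)
        assert probs.shape == (2, 45)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_block_parameters_double_with_block_count(self):
        tok = Tokenizer(max_length=32)
        e2 = TransformerEncoder(TINY, tok.vocab_size, tok.PAD)
        cfg4 = EncoderConfig(n_blocks=4, d_model=16, n_heads=2, d_feedforward=32,
                             dropout=0.0, max_length=32)
        e4 = TransformerEncoder(cfg4, tok.vocab_size, tok.PAD)
        assert e4.block_parameter_count() == 2 * e2.block_parameter_count()

    def test_invalid_width_head_combination_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(d_model=50, n_heads=8)


class TestSplits:
    @pytest.mark.parametrize(
        "n,frac,n_train,n_test",
        [(100, 0.95, 95, 5), (100, 0.80, 80, 20), (101, 0.95, 95, 6), (101, 0.80, 80, 21)],
    )
    def test_floor_convention(self, n, frac, n_train, n_test):
        tr, te = split_indices(n, SplitSpec(frac, seed=3))
        assert (len(tr), len(te)) == (n_train, n_test)
        assert sorted(np.concatenate([tr, te])) == list(range(n))

    def test_stratified_split_preserves_classes(self):
        labels = np.repeat(np.arange(5), 20)
        tr, te = stratified_split_indices(labels, SplitSpec(0.80, seed=1))
        assert len(tr) == 80 and len(te) == 20
        for c in range(5):
            assert (labels[tr] == c).sum() == 16
            assert (labels[te] == c).sum() == 4

    def test_stratified_split_never_empties_a_training_class(self):
        labels = np.array([0] * 50 + [1] * 2 + [2] * 3)
        tr, _ = stratified_split_indices(labels, SplitSpec(0.80, seed=0))
        for c in (0, 1, 2):
            assert (labels[tr] == c).sum() >= 1

    def test_same_seed_reproduces_split(self):
        a = split_indices(60, SplitSpec(0.8, seed=9))
        b = split_indices(60, SplitSpec(0.8, seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        enc, tok = tiny_encoder(seed=4)
        cfg = ClassifierConfig(n_classes=6, d_attn=16, n_heads=2, hidden_dims=(16, 12, 8))
        head = ClassificationHead(cfg, d_in=16, seed=5)
        mlm = MLMHead(16, tok.vocab_size, seed=6)
        p = tmp_path / "model.npz"
        save_checkpoint(p, enc, tok, head=head, mlm_head=mlm)
        enc2, tok2, head2, mlm2 = load_checkpoint(p)
        seqs = SequenceSet([random_protein(rng, 15, f"s{i}") for i in range(3)])
        np.testing.assert_allclose(embed(enc, seqs, tok), embed(enc2, seqs, tok2), atol=1e-6)
        ids = tokenize(seqs[0], tok)[None, :]
        h = enc.forward(ids)
        valid = tok.is_residue_id(ids)
        np.testing.assert_allclose(
            head.predict_probs(h, valid), head2.predict_probs(enc2.forward(ids), valid),
            atol=1e-6,
        )
        np.testing.assert_allclose(mlm.forward(h[0]), mlm2.forward(h[0]), atol=1e-6)


class TestAdam:
    def test_descends_a_quadratic(self):
        from ssnplm.nn.layers import Module

        class Quad(Module):
            def __init__(self):
                super().__init__()
                self.p["w"] = np.array([5.0, -3.0], dtype=np.float32)

        q = Quad()
        opt = Adam(q, lr=0.1)
        for _ in range(300):
            q.zero_grad()
            q.g["w"] += 2 * q.p["w"]
            opt.step()
        assert np.abs(q.p["w"]).max() < 1e-2
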