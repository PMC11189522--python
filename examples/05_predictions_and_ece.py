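"""Cluster predictions, ECE perplexity, and 2-D embedding projection.

ECE = exp(mean over test sequences of -ln p(true cluster)).  It is 1 when
every prediction is confidently correct and K when predictions are uniform
over K clusters, so it measures confidence, not just correctness.
"""

import numpy as np

from ssnplm import FamilyConfig, generate_families
from ssnplm.nn import EncoderConfig
from ssnplm.plm import (
    ClassifierConfig,
    Prediction,
    SplitSpec,
    accuracy,
    ece_perplexity,
    embed,
    predict,
    pretrain_mlm,
    project_2d,
    train_classifier,
)
from ssnplm.plm.train import OptimSettings, build_classifier

# analytic anchors of the ECE scale over 45 clusters
labels45 = {f"s{i}": (i % 45) + 1 for i in range(50)}
onehot = [Prediction.from_probabilities(s, np.eye(45)[y - 1]) for s, y in labels45.items()]
uniform = [Prediction.from_probabilities(s, np.full(45, 1 / 45)) for s in labels45]
print(f"ECE, deterministic-correct over 45 clusters: {ece_perplexity(onehot, labels45):.4f}")
print(f"ECE, uniform over 45 clusters:               {ece_perplexity(uniform, labels45):.4f}")

# a small trained model to score
corpus = generate_families(FamilyConfig(5, 20, 80, 0.12, seed=9))
enc_cfg = EncoderConfig(2, 32, 2, 128, 0.0, 96)
encoder, _, tok, _ = pretrain_mlm(
    corpus.sequences, enc_cfg,
    settings=OptimSettings(epochs=5, batch_size=32, learning_rate=1e-3), seed=1)
head = build_classifier(
    ClassifierConfig(n_classes=5, d_attn=32, n_heads=2, hidden_dims=(64, 48, 32)),
    d_model=32, seed=2)
head, report = train_classifier(encoder, head, corpus,
                                split=SplitSpec(0.80, seed=3), tok=tok, seed=3)
preds = predict(encoder, head, corpus.sequences, tok)
print(f"whole-corpus accuracy {accuracy(preds, corpus.truth):.3f}, "
      f"ECE {ece_perplexity(preds, corpus.truth):.3f} (1 = perfect, 5 = guessing)")

coords = project_2d(embed(encoder, corpus.sequences, tok), seed=4)
print(f"UMAP projection of the embeddings: {coords.shape[0]} points in 2-D "
      f"(families form separate islands when the encoder has learned)")
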