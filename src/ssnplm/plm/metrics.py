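"""Classifier evaluation: accuracy and exponential cross-entropy (ECE).

ECE is the perplexity ``exp( (1/n) * sum_i CE(s_i, y_i) )`` with natural-log
cross-entropy ``CE(s_i, y_i) = -ln p_i(y_i)``: 1 for deterministic correct
predictions, K for uniform predictions over K classes.  Probabilities are
clamped at 1e-12 before the log so a confidently wrong prediction yields a
large finite perplexity rather than infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class Prediction:
    """Per-sequence class distribution over cluster ids 1..K."""

    id: str
    probabilities: np.ndarray
    predicted_cluster: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("probabilities must be a 1-D vector")
        if (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities of {self.id!r} must be a distribution")

    @classmethod
    def from_probabilities(cls, sid: str, probs: np.ndarray) -> "Prediction":
        """Argmax with deterministic tie-break to the smallest cluster id."""
        probs = np.asarray(probs, dtype=float)
        return cls(sid, probs, int(np.argmax(probs)) + 1)


@dataclass(frozen=True)
class EvalReport:
    """Held-out evaluation: size, accuracy, ECE perplexity."""

    n: int
    accuracy: float
    ece: float

    def __str__(self) -> str:
        return f"n={self.n}  accuracy={self.accuracy:.4f}  ECE={self.ece:.4f}"


def _label_of(labels, sid: str) -> int:
    mapping = getattr(labels, "labels", labels)
    if sid not in mapping:
        raise KeyError(f"no label for sequence {sid!r}")
    return mapping[sid]


def ece_perplexity(preds: list[Prediction], labels) -> float:
    """Exponential cross-entropy of true labels under the predictions.

    ``labels`` is a ClusterLabelSet or a plain id -> cluster_id mapping
    (1-based cluster ids).
    """
    if not preds:
        raise ValueError("need at least one prediction")
    ces = []
    for pr in preds:
        y = _label_of(labels, pr.id)
        if not (1 <= y <= len(pr.probabilities)):
            raise ValueError(f"label {y} of {pr.id!r} outside 1..{len(pr.probabilities)}")
        p = max(float(pr.probabilities[y - 1]), PROB_FLOOR)
        ces.append(-np.log(p))
    return float(np.exp(np.mean(ces)))


def accuracy(preds: list[Prediction], labels) -> float:
    """Fraction of predictions whose argmax cluster equals the true label."""
    if not preds:
        raise ValueError("need at least one prediction")
    hits = sum(pr.predicted_cluster == _label_of(labels, pr.id) for pr in preds)
    return hits / len(preds)
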