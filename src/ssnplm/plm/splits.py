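"""Deterministic train/test splitting.

Convention (fixed so split sizes are reproducible): the training side gets
``floor(train_fraction * n)`` items, clamped to [1, n-1].  At n = 100 the
95/5 and 80/20 splits are exact; at n = 101 they give 95/6 and 80/21.
The stratified variant reaches the same global training count by
largest-remainder allocation across classes, so no class is emptied on the
training side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SplitSpec:
    """Train fraction and shuffling seed."""

    train_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")

    def n_train(self, n: int) -> int:
        return min(max(math.floor(self.train_fraction * n), 1), n - 1)


def split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Random unstratified split of range(n) into (train, test) indices."""
    if n < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    k = spec.n_train(n)
    return np.sort(perm[:k]), np.sort(perm[k:])


def stratified_split_indices(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split: class proportions preserved as closely as integer
    counts allow, while every class keeps at least one training item."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(spec.seed)
    k_total = spec.n_train(n)
    classes, counts = np.unique(labels, return_counts=True)
    quota = spec.train_fraction * counts
    base = np.maximum(np.floor(quota).astype(int), 1)
    base = np.minimum(base, counts)
    # distribute the remaining slots by largest fractional remainder
    remainder = quota - np.floor(quota)
    order = np.argsort(-remainder, kind="stable")
    short = k_total - int(base.sum())
    i = 0
    while short != 0 and i < 10 * len(classes):
        c = order[i % len(classes)]
        if short > 0 and base[c] < counts[c]:
            base[c] += 1
            short -= 1
        elif short < 0 and base[c] > 1:
            base[c] -= 1
            short += 1
        i += 1
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for c, k in zip(classes, base):
        idx = np.nonzero(labels == c)[0]
        perm = rng.permutation(len(idx))
        train.append(idx[perm[:k]])
        test.append(idx[perm[k:]])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))
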