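"""Shared fixtures: tiny deterministic sequence sets and corpora."""

from __future__ import annotations

import numpy as np
import pytest

from ssnplm import ProteinSequence, SequenceSet

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int, sid: str = "s") -> ProteinSequence:
    return ProteinSequence(sid, "".join(rng.choice(list(AA), length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def three_seqs() -> SequenceSet:
    return SequenceSet(
        [
            ProteinSequence("a", "ACDEFGHIKL"),
            ProteinSequence("b", "WYWYWYWYWY"),
            ProteinSequence("c", "MNPQRSTVWY"),
        ]
    )
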