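"""Pairwise alignment identity and greedy redundancy reduction.

Percent identity is computed from an optimal pairwise alignment
(Smith–Waterman local or Needleman–Wunsch global, affine gaps, BLOSUM62 by
default) as ``identical columns / length of the shorter sequence`` — the
CD-HIT convention.  Normalising by the shorter sequence rather than by the
alignment footprint matters for thresholding: unrelated sequences often
share a short high-scoring local footprint whose *footprint* identity is
large (0.3-0.5 on random proteins), while their shorter-sequence identity
stays near the random background, so a 40% network threshold separates
families only under this convention.  A gap of length L costs
``gap_open + (L - 1) * gap_extend``.

Redundancy reduction is greedy incremental clustering in decreasing length
order (CD-HIT style, but with full alignment identity rather than k-mer
short-circuits): a sequence joins the first representative it matches at or
above the identity threshold, otherwise it founds a new representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .seqio import ProteinSequence, SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentParams",
    "IdentityResult",
    "RedundancyParams",
    "align_identity",
    "reduce_redundancy",
]


def _blosum62() -> balign.SubstitutionMatrix:
    return balign.SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment scoring scheme.

    mode
        ``"local"`` (Smith–Waterman) or ``"global"`` (Needleman–Wunsch).
    matrix_name
        Name of the substitution matrix (any NCBI-format matrix biotite
        ships; default BLOSUM62).
    gap_open, gap_extend
        Affine gap penalties as nonnegative magnitudes (BLAST protein
        defaults 11/1); a length-L gap costs ``open + (L-1)*extend``.
    """

    mode: Literal["local", "global"] = "local"
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def substitution_matrix(self) -> balign.SubstitutionMatrix:
        if self.matrix_name.upper() == "BLOSUM62":
            return _blosum62()
        alph = bseq.ProteinSequence.alphabet
        return balign.SubstitutionMatrix(alph, alph, self.matrix_name.upper())


@dataclass(frozen=True)
class IdentityResult:
    """Identity of one optimal pairwise alignment.

    ``identity = identical_columns / min(len(a), len(b))`` (the CD-HIT
    convention); ``aligned_columns`` is the alignment footprint including
    gap columns.  Identity is 0 when the optimal local alignment is empty.
    """

    identity: float
    aligned_columns: int
    identical_columns: int
    raw_score: int


@dataclass(frozen=True)
class RedundancyParams:
    """Identity cutoff for redundancy reduction (default 0.80)."""

    threshold: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")


def _to_biotite(s: ProteinSequence) -> bseq.ProteinSequence:
    try:
        return bseq.ProteinSequence(s.residues)
    except Exception as exc:  # pragma: no cover - guarded by seqio invariants
        raise ValueError(f"sequence {s.id!r} outside scored alphabet: {exc}") from exc


def align_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    params: AlignmentParams | None = None,
) -> IdentityResult:
    """Optimal-alignment percent identity between two sequences.

    Symmetric in its arguments: the pair is put into a canonical order
    before aligning, since the aligner's tie-break between co-optimal
    alignments (which can differ in identical columns) depends on argument
    order.  The optimal score itself is order-invariant.
    """
    params = params or AlignmentParams()
    if b.residues < a.residues:
        a, b = b, a
    matrix = params.substitution_matrix()
    alns = balign.align_optimal(
        _to_biotite(a),
        _to_biotite(b),
        matrix,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=params.mode == "local",
        max_number=1,
    )
    aln = alns[0]
    n_cols = len(aln)
    min_len = min(len(a), len(b))
    if n_cols == 0 or (params.mode == "local" and aln.score <= 0):
        return IdentityResult(0.0, 0, 0, int(aln.score))
    codes = balign.get_codes(aln)
    identical = int(((codes[0] == codes[1]) & (codes[0] != -1)).sum())
    return IdentityResult(identical / min_len, n_cols, identical, int(aln.score))


def _pick_mode(a: ProteinSequence, b: ProteinSequence, params: AlignmentParams) -> AlignmentParams:
    """Redundancy-step mode rule: global when lengths differ by < 20%, else local."""
    la, lb = len(a), len(b)
    rel = abs(la - lb) / max(la, lb)
    mode = "global" if rel < 0.20 else "local"
    if mode == params.mode:
        return params
    return AlignmentParams(mode, params.matrix_name, params.gap_open, params.gap_extend)


def reduce_redundancy(
    seqs: SequenceSet,
    params: RedundancyParams | None = None,
    align: AlignmentParams | None = None,
) -> tuple[SequenceSet, dict[str, str]]:
    """Greedy longest-first redundancy reduction at an identity cutoff.

    Sequences are visited in decreasing length (input order breaks ties);
    each joins the first existing representative with identity >= threshold,
    else becomes a new representative.  Returns the representatives (in
    visitation order) and a membership map id -> representative id, with
    every representative mapping to itself.

    Postconditions: every member has identity >= threshold to its
    representative and any two representatives have identity < threshold.
    """
    params = params or RedundancyParams()
    align = align or AlignmentParams(mode="global")
    if len(seqs) == 0:
        raise ValueError("reduce_redundancy requires a non-empty SequenceSet")

    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: list[ProteinSequence] = []
    membership: dict[str, str] = {}
    for idx in order:
        s = seqs[idx]
        assigned = False
        for rep in reps:
            res = align_identity(s, rep, _pick_mode(s, rep, align))
            if res.identity >= params.threshold:
                membership[s.id] = rep.id
                assigned = True
                break
        if not assigned:
            reps.append(s)
            membership[s.id] = s.id
    logger.info(
        "redundancy reduction: %d sequences -> %d representatives at %.2f",
        len(seqs), len(reps), params.threshold,
    )
    return SequenceSet(reps, source=seqs.source), membership
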