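"""Independent brute-force oracles used by the test suite.

The alignment oracle is a plain-Python affine-gap dynamic programme
(three-state Gotoh) written separately from the package's alignment path
and scored with Biopython's BLOSUM62 tables.  Because co-optimal
alignments can differ in identity, the oracle reports the optimal score
plus the full set of (identical_columns, aligned_columns) pairs achievable
by any optimal-score alignment; an implementation is correct iff its score
matches exactly and its identity pair lies in that set.

Conventions (matching the package): a gap of length L costs
open + (L - 1) * extend; a local alignment starts and ends on a
substitution column and never includes zero-score prefixes.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

NEG = float("-inf")


def oracle_align(
    a: str,
    b: str,
    mode: str = "local",
    gap_open: int = 11,
    gap_extend: int = 1,
    matrix_name: str = "BLOSUM62",
) -> tuple[float, set[tuple[int, int]]]:
    """Optimal alignment score and the set of (identical, columns) pairs
    over all optimal alignments.  An empty local optimum yields {(0, 0)}."""
    mat = substitution_matrices.load(matrix_name)
    s = lambda x, y: float(mat[x, y])  # noqa: E731
    n, m = len(a), len(b)
    local = mode == "local"

    # state 0 = M (a[i-1]~b[j-1]), 1 = Ix (a[i-1]~gap), 2 = Iy (gap~b[j-1])
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    if local:
        M[:, 0] = 0.0
        M[0, :] = 0.0

    def gap_step(prev_m: float, prev_same: float, prev_other: float) -> float:
        return max(prev_m - gap_open, prev_same - gap_extend, prev_other - gap_open)

    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0:
                Ix[i, j] = gap_step(M[i - 1, j], Ix[i - 1, j], Iy[i - 1, j])
            if j > 0:
                Iy[i, j] = gap_step(M[i, j - 1], Iy[i, j - 1], Ix[i, j - 1])
            if i > 0 and j > 0:
                sub = s(a[i - 1], b[j - 1])
                best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
                M[i, j] = sub + best_prev
                if local:
                    M[i, j] = max(M[i, j], 0.0)

    tabs = (M, Ix, Iy)
    sys.setrecursionlimit(100_000)

    @lru_cache(maxsize=None)
    def back(state: int, i: int, j: int) -> frozenset[tuple[int, int]]:
        """(identical, columns) pairs over all optimal path prefixes ending
        at cell (state, i, j), inclusive of that cell's column."""
        score = tabs[state][i, j]
        out: set[tuple[int, int]] = set()
        if state == 0:
            sub = s(a[i - 1], b[j - 1])
            ident = 1 if a[i - 1] == b[j - 1] else 0
            prev = score - sub
            starts_here = (i == 1 and j == 1) if not local else True
            if prev == 0.0 and starts_here and (local or M[0, 0] == 0.0):
                out.add((ident, 1))
            if not (local and prev == 0.0):  # local paths stop at zero
                for ps in range(3):
                    v = tabs[ps][i - 1, j - 1]
                    if v != NEG and v == prev and not (i == 1 and j == 1):
                        out |= {(pi + ident, pc + 1) for pi, pc in back(ps, i - 1, j - 1)}
            return frozenset(out)
        if state == 1:  # consumes a[i-1] against a gap
            preds = ((0, gap_open), (1, gap_extend), (2, gap_open))
            pi_, pj_ = i - 1, j
        else:  # consumes b[j-1] against a gap
            preds = ((0, gap_open), (2, gap_extend), (1, gap_open))
            pi_, pj_ = i, j - 1
        for ps, cost in preds:
            v = tabs[ps][pi_, pj_]
            if v == NEG or v != score + cost:
                continue
            if ps == 0 and pi_ == 0 and pj_ == 0:
                out.add((0, 1))  # global alignment beginning with a gap run
            elif ps == 0 and (pi_ == 0 or pj_ == 0):
                continue  # local M=0 boundary cells are not path cells
            else:
                out |= {(pi, pc + 1) for pi, pc in back(ps, pi_, pj_)}
        return frozenset(out)

    if local:
        best = float(M.max())
        if best <= 0.0:
            return 0.0, {(0, 0)}
        pairs: set[tuple[int, int]] = set()
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if M[i, j] == best:
                    pairs |= back(0, i, j)
        return best, pairs

    best = max(M[n, m], Ix[n, m], Iy[n, m])
    pairs = set()
    for st in range(3):
        if tabs[st][n, m] == best:
            pairs |= set(back(st, n, m))
    return float(best), pairs


def oracle_identity(a: str, b: str, **kw) -> set[float]:
    """Identities of all optimal alignments (0.0 for an empty local optimum)."""
    _, pairs = oracle_align(a, b, **kw)
    return {(i / c if c else 0.0) for i, c in pairs}
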