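"""Semi-global pairwise alignment with an explicit percent-identity definition.

Identity between a query and a reference is computed from an optimal
semi-global alignment — terminal gaps are free on both sequences — under
match +1 / mismatch −1 / gap −2 scoring.  Percent identity is matches
divided by the number of alignment columns, where columns lying in the
terminal-gap overhangs are excluded; IUPAC-compatible base pairs count as
matches.  This replaces heuristic local-alignment identity (BLAST-style)
with a deterministic, tool-independent definition.

The dynamic program runs on 4-bit base encodings in numba-compiled
kernels; traceback ties break deterministically (diagonal, then up, then
left), and the start cell prefers the bottom-right corner, then the bottom
row right-to-left, then the right column bottom-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import iupac


@dataclass
class AlignmentResult:
    score: float
    matches: int
    columns: int  # alignment columns excluding terminal overhangs
    identity: float  # percent
    a_span: tuple[int, int]  # 1-based inclusive aligned span of a ((0,0) if empty)
    b_span: tuple[int, int]
    #: for each 1-based position of b inside the aligned span, the aligned
    #: character of a ('-' for a gap); positions in overhangs are absent.
    b_to_a: dict[int, str]


@njit(cache=True)
def _fill(am, bm, match, mismatch, gap):  # pragma: no cover - compiled
    la, lb = am.shape[0], bm.shape[0]
    H = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        ai = am[i - 1]
        for j in range(1, lb + 1):
            s = match if (ai & bm[j - 1]) != 0 else mismatch
            h = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            if u > h:
                h = u
            left = H[i, j - 1] + gap
            if left > h:
                h = left
            H[i, j] = h
    return H


@njit(cache=True)
def _traceback(H, am, bm, match, mismatch, gap):  # pragma: no cover - compiled
    la, lb = am.shape[0], bm.shape[0]
    best_i, best_j = la, lb
    best = H[la, lb]
    for j in range(lb - 1, -1, -1):
        if H[la, j] > best:
            best, best_i, best_j = H[la, j], la, j
    for i in range(la - 1, -1, -1):
        if H[i, lb] > best:
            best, best_i, best_j = H[i, lb], i, lb
    i, j = best_i, best_j
    matches = 0
    columns = 0
    # bmap[j] = 0-based index of a aligned to b position j, -1 for a gap,
    # -2 outside the aligned span
    bmap = np.full(lb + 1, -2, dtype=np.int32)
    while i > 0 and j > 0:
        compat = (am[i - 1] & bm[j - 1]) != 0
        s = match if compat else mismatch
        h = H[i, j]
        if h == H[i - 1, j - 1] + s:
            if compat:
                matches += 1
            bmap[j] = i - 1
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + gap:
            i -= 1
        else:
            bmap[j] = -1
            j -= 1
        columns += 1
    return best, matches, columns, i, j, best_i, best_j, bmap


def semiglobal_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Optimal semi-global alignment of two nucleotide sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    am = iupac.encode(a)
    bm = iupac.encode(b)
    H = _fill(am, bm, float(match), float(mismatch), float(gap))
    score, matches, columns, i0, j0, bi, bj, bmap = _traceback(
        H, am, bm, float(match), float(mismatch), float(gap)
    )
    b_to_a = {}
    for j in range(1, len(b) + 1):
        v = int(bmap[j])
        if v == -1:
            b_to_a[j] = "-"
        elif v >= 0:
            b_to_a[j] = a[v]
    identity = 100.0 * matches / columns if columns else 0.0
    return AlignmentResult(
        score=float(score),
        matches=int(matches),
        columns=int(columns),
        identity=identity,
        a_span=(i0 + 1, bi) if bi > i0 else (0, 0),
        b_span=(j0 + 1, bj) if bj > j0 else (0, 0),
        b_to_a=b_to_a,
    )


def pairwise_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity of the optimal semi-global alignment of a and b."""
    a = iupac.normalize(a)
    b = iupac.normalize(b)
    if len(a) == len(b):
        # a gapless all-compatible alignment attains the maximal score
        if all(iupac.compatible(x, y) for x, y in zip(a, b)):
            return 100.0
    return semiglobal_align(a, b, match, mismatch, gap).identity
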