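"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written without reference to the package's
vectorised implementations: per-column set logic for diagnostics, exhaustive
alignment enumeration for identity, direct formula evaluation for diversity.
"""

from __future__ import annotations

import math
from functools import lru_cache

EXPAND = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
    "-": set(), ".": set(),
}


def diagnostic_columns_oracle(rows_focal, rows_other):
    """0-based columns where the focal rows share one unambiguous base that
    no other row's expansion contains (gaps carry no state)."""
    out = []
    ncol = len(rows_focal[0])
    for j in range(ncol):
        states = {r[j] for r in rows_focal}
        if len(states) != 1:
            continue
        s = states.pop()
        if s not in "ACGT":
            continue
        if any(s in EXPAND[r[j]] for r in rows_other):
            continue
        out.append(j)
    return out


def enumerate_alignments(a, b):
    """All monotone global alignments of a and b as lists of column pairs
    ((i or None), (j or None)) with 0-based indices."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return [[]]
        outs = []
        if i < len(a) and j < len(b):
            outs += [[(i, j)] + rest for rest in rec(i + 1, j + 1)]
        if i < len(a):
            outs += [[(i, None)] + rest for rest in rec(i + 1, j)]
        if j < len(b):
            outs += [[(None, j)] + rest for rest in rec(i, j + 1)]
        return outs

    result = rec(0, 0)
    rec.cache_clear()
    return result


def score_alignment(cols, a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """(score, matches, core_columns) of an alignment under semi-global
    scoring: runs of terminal gap columns at either end are free and
    excluded from the core."""
    def gap_kind(col):
        if col[0] is None:
            return "a"  # gap in a (overhang of b)
        if col[1] is None:
            return "b"
        return None

    # a free terminal run consists of gap columns of one consistent kind:
    # both sequences may have free terminal gaps, but an end where *both*
    # overhang simultaneously is local alignment, not semi-global
    start = 0
    end = len(cols)
    lead = gap_kind(cols[0]) if cols else None
    while start < end and lead is not None and gap_kind(cols[start]) == lead:
        start += 1
    trail = gap_kind(cols[end - 1]) if end > start else None
    while end > start and trail is not None and gap_kind(cols[end - 1]) == trail:
        end -= 1
    core = cols[start:end]
    score = 0.0
    matches = 0
    for i, j in core:
        if i is None or j is None:
            score += gap
        elif EXPAND[a[i]] & EXPAND[b[j]]:
            score += match
            matches += 1
        else:
            score += mismatch
    return score, matches, len(core)


def best_semiglobal(a, b):
    """Optimal score and the set of (matches, columns) over all co-optimal
    semi-global alignments, by exhaustive enumeration (tiny inputs only)."""
    best = -math.inf
    outcomes = set()
    for cols in enumerate_alignments(a, b):
        score, m, c = score_alignment(cols, a, b)
        if score > best:
            best = score
            outcomes = {(m, c)}
        elif score == best:
            outcomes.add((m, c))
    return best, outcomes


def shannon_oracle(counts):
    total = math.fsum(counts)
    h = 0.0
    for n in counts:
        if n > 0:
            p = n / total
            h -= p * math.log(p)
    return h


def rarefaction_oracle(counts, depth):
    """E[S_d] by direct combinatorial evaluation with exact integers."""
    counts = [int(n) for n in counts if n > 0]
    N = sum(counts)
    total = 0.0
    denom = math.comb(N, depth)
    for n in counts:
        absent = math.comb(N - n, depth) if N - n >= depth else 0
        total += 1.0 - absent / denom
    return total
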