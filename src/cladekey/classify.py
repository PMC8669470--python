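"""Assignment of environmental ASVs to classification units.

An ASV is assigned to the unit whose representative it matches best,
subject to two conditions echoing a representative-database search with
manual confirmation: (1) best percent identity at or above ``min_identity``
(default 100 — exact identity to a representative), and (2) every
diagnostic column of the winning unit that falls inside the aligned
overlap must be matched by a compatible ASV base.  Ties between units at
the decision boundary are reported as "ambiguous", never broken silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import iupac
from .io import AsvTable
from .key import DiagnosticKey
from .pairwise import semiglobal_align

_EPS = 1e-9


@dataclass
class ClassificationResult:
    asv_id: str
    unit: str  # unit label, "unclassified" or "ambiguous"
    mode: str  # "exact" | "diagnostic" | "unclassified" | "ambiguous"
    identity: float  # percent identity to the best representative
    diag_matched: int
    diag_total: int
    runner_up: str | None = None
    runner_identity: float | None = None
    note: str = ""


def _score_against_unit(
    seq: str, unit, match: float, mismatch: float, gap: float
) -> tuple[float, int, int]:
    """Best (identity, diag_matched, diag_total) of seq over unit representatives.

    Diagnostics are checked in the alignment against the representative that
    achieves the best identity; only diagnostics inside the aligned overlap
    count toward diag_total.
    """
    diag = dict(unit.diagnostics)
    best_ident = -1.0
    best = (0.0, 0, 0)
    for rid, rep in unit.representatives.items():
        col_of_pos = unit.rep_pos_maps[rid]  # degapped pos-1 -> region column
        pos_of_col = {c: p + 1 for p, c in enumerate(col_of_pos)}
        if len(seq) == len(rep) and all(
            iupac.compatible(x, y) for x, y in zip(seq, rep)
        ):
            # exact (IUPAC-compatible end-to-end) match: all diagnostics in
            # the overlap are matched by construction
            return (100.0, len(diag), len(diag))
        res = semiglobal_align(seq, rep, match, mismatch, gap)
        if res.identity > best_ident:
            matched = total = 0
            for col, state in diag.items():
                p = pos_of_col.get(col)
                if p is None or p not in res.b_to_a:
                    continue  # diagnostic outside this rep / aligned overlap
                total += 1
                if iupac.compatible(res.b_to_a[p], state):
                    matched += 1
            best_ident = res.identity
            best = (res.identity, matched, total)
    return best


def classify_asv(
    seq: str,
    key: DiagnosticKey,
    min_identity: float = 100.0,
    asv_id: str = "asv",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> ClassificationResult:
    """Classify one ASV sequence against a diagnostic key."""
    if not key.units or not any(u.representatives for u in key.units):
        raise ValueError("key has no units with representatives")
    seq = iupac.normalize(seq)
    rep_lens = [len(r) for u in key.units for r in u.representatives.values()]
    if len(seq) < 0.5 * (sum(rep_lens) / len(rep_lens)):
        return ClassificationResult(
            asv_id, "unclassified", "unclassified", 0.0, 0, 0,
            note="query shorter than half the representative length",
        )
    scored = []
    for u in key.units:
        ident, dm, dt = _score_against_unit(seq, u, match, mismatch, gap)
        scored.append((u.label, ident, dm, dt))
    scored.sort(key=lambda t: -t[1])
    best_label, best_ident, dm, dt = scored[0]
    runner = scored[1] if len(scored) > 1 else None
    passing = [
        t for t in scored
        if t[1] >= min_identity - _EPS and t[2] == t[3]
    ]
    if not passing:
        return ClassificationResult(
            asv_id, "unclassified", "unclassified", best_ident, dm, dt,
            runner_up=runner[0] if runner else None,
            runner_identity=runner[1] if runner else None,
        )
    top = passing[0][1]
    tied = [t for t in passing if abs(t[1] - top) < _EPS]
    if len(tied) > 1:
        return ClassificationResult(
            asv_id, "ambiguous", "ambiguous", top, tied[0][2], tied[0][3],
            runner_up=tied[1][0], runner_identity=tied[1][1],
            note="tie between units " + ",".join(t[0] for t in tied),
        )
    label, ident, dm, dt = tied[0]
    mode = "exact" if ident >= 100.0 - _EPS else "diagnostic"
    return ClassificationResult(
        asv_id, label, mode, ident, dm, dt,
        runner_up=runner[0] if runner else None,
        runner_identity=runner[1] if runner else None,
    )


def classify_table(
    asvs: AsvTable,
    key: DiagnosticKey,
    min_identity: float = 100.0,
    **align_params: float,
) -> pd.DataFrame:
    """Classify every ASV of a table; returns a tidy per-ASV frame.

    Columns: asv_id, unit, mode, identity, diag_matched, diag_total,
    runner_up, runner_identity, note.  Deterministic given its inputs.
    """
    rows = [
        classify_asv(asvs.sequences[aid], key, min_identity, asv_id=aid, **align_params)
        for aid in asvs.asv_ids
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def classification_summary(assign: pd.DataFrame) -> dict[str, int]:
    return assign["mode"].value_counts().to_dict()


def screen_external(
    asvs: AsvTable, query: str, threshold: float = 98.0
) -> pd.DataFrame:
    """Return ASVs/OTUs whose identity to the query is strictly above threshold.

    The screen used to ask whether a clade has close relatives in an
    external data set (e.g. a freshwater OTU catalogue).
    """
    from .pairwise import pairwise_identity

    query = iupac.normalize(query)
    hits = []
    for aid in asvs.asv_ids:
        ident = pairwise_identity(asvs.sequences[aid], query)
        if ident > threshold:
            hits.append((aid, ident))
    return pd.DataFrame(hits, columns=["asv_id", "identity"])
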