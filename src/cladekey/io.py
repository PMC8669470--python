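"""Reference-alignment, clade-label and ASV-table input/output.

The curated reference product consumed here is a gapped multiple alignment
of full-length 18S rRNA gene sequences together with a table assigning each
sequence to a named clade; building that alignment (MAFFT/trimAl) and the
tree that supports the clades are upstream of this package.  The marker
subregion used for classification (the V9 hypervariable region) is cut out
of the alignment either by explicit column coordinates or by locating the
amplification primers in the (degapped) reference rows.

All alignment-column and degapped-position coordinates are 1-based and
inclusive, following GenBank feature convention.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import iupac


@dataclass
class ReferenceAlignment:
    """A gapped multiple alignment with unique, ordered sequence ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment is empty")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        length = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise ValueError(
                    f"ragged alignment: sequence {sid!r} has length {len(s)}, "
                    f"expected {length}"
                )
            iupac.validate(s, name=f"sequence {sid!r}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def row(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class CladeMap:
    """id → clade label assignments over an alignment's sequences."""

    assignments: dict[str, str]

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.assignments.values():
            seen.setdefault(c)
        return list(seen)

    def members(self, clade: str) -> list[str]:
        return [i for i, c in self.assignments.items() if c == clade]

    def sizes(self) -> dict[str, int]:
        return {c: len(self.members(c)) for c in self.clades}


@dataclass
class RegionSlice:
    """A column span of the alignment with per-sequence degapped subsequences.

    ``column_map[k]`` is the original alignment column of region column
    ``k+1``; ``pos_maps[sid][p]`` is the region column (1-based) of degapped
    position ``p+1`` of sequence ``sid``.
    """

    start_col: int
    end_col: int
    aligned_rows: dict[str, str]
    column_map: list[int]
    degapped: dict[str, str] = field(init=False)
    pos_maps: dict[str, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start_col <= self.end_col):
            raise ValueError("invalid region span")
        self.degapped = {}
        self.pos_maps = {}
        for sid, row in self.aligned_rows.items():
            pos_map = [k + 1 for k, c in enumerate(row) if c not in iupac.GAP_CHARS]
            self.degapped[sid] = iupac.degap(row)
            self.pos_maps[sid] = pos_map

    @property
    def width(self) -> int:
        return self.end_col - self.start_col + 1


def read_alignment(path: str | Path) -> ReferenceAlignment:
    """Read an aligned FASTA file, normalising case and U→T.

    Raises on an empty file or ragged sequence lengths (the offending id is
    named).
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(iupac.normalize(str(rec.seq)))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceAlignment(ids, seqs)


def write_alignment(aln: ReferenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def load_clade_map(path: str | Path, aln: ReferenceAlignment) -> CladeMap:
    """Load a two-column id<TAB>clade table validated against the alignment.

    Alignment ids absent from the table are left unassigned (and excluded
    from key detection); a label for an id not in the alignment, or two
    conflicting labels for one id, is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "id" in cols and "clade" in cols:
        df.columns = cols
    else:  # headerless two-column file
        df = pd.read_csv(path, sep="\t", header=None, names=["id", "clade"], dtype=str)
    known = set(aln.ids)
    assignments: dict[str, str] = {}
    for _, r in df.iterrows():
        sid, clade = r["id"], r["clade"]
        if sid not in known:
            raise ValueError(f"clade label for unknown sequence id {sid!r}")
        if sid in assignments and assignments[sid] != clade:
            raise ValueError(
                f"conflicting clade labels for {sid!r}: "
                f"{assignments[sid]!r} vs {clade!r}"
            )
        assignments[sid] = clade
    # preserve alignment order
    ordered = {i: assignments[i] for i in aln.ids if i in assignments}
    return CladeMap(ordered)


def write_clade_map(cm: CladeMap, path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(cm.assignments), "clade": list(cm.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region extraction


def _find_primer(degapped: str, primer: str, max_mismatch: int) -> tuple[int, int] | None:
    """Best primer placement in a degapped row; (start, mismatches), 0-based.

    Degenerate primer positions match any compatible base.  Returns the
    lowest-mismatch, leftmost hit at ≤ max_mismatch, else None.
    """
    lp, ls = len(primer), len(degapped)
    if lp > ls:
        return None
    pm = iupac.encode(primer)
    sm = iupac.encode(degapped)
    best: tuple[int, int] | None = None
    for off in range(ls - lp + 1):
        mism = int(np.count_nonzero((pm & sm[off : off + lp]) == 0))
        if mism <= max_mismatch and (best is None or mism < best[1]):
            best = (off, mism)
            if mism == 0:
                break
    return best


def extract_region(
    aln: ReferenceAlignment,
    *,
    cols: tuple[int, int] | None = None,
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
    max_mismatch: int = 2,
) -> RegionSlice:
    """Cut a subregion out of the alignment.

    Either an explicit 1-based inclusive column span is given, or the
    forward/reverse primer pair is located by a gap-elided scan of each row
    (the reverse primer is matched as its reverse complement).  The region
    comprises the columns strictly between the forward-primer end and the
    reverse-primer start; all rows in which both primers are found must
    agree on that span.
    """
    if cols is not None:
        start, end = cols
        if not (1 <= start <= end <= aln.length):
            raise ValueError(
                f"explicit span {start}:{end} outside alignment columns 1:{aln.length}"
            )
    else:
        if not (fwd_primer and rev_primer):
            raise ValueError("provide either cols=(start,end) or both primers")
        fwd = iupac.normalize(fwd_primer)
        rev_rc = iupac.reverse_complement(iupac.normalize(rev_primer))
        spans: set[tuple[int, int]] = set()
        for sid, row in zip(aln.ids, aln.seqs):
            deg = iupac.degap(row)
            # map degapped index -> alignment column (1-based)
            col_of = [k + 1 for k, c in enumerate(row) if c not in iupac.GAP_CHARS]
            fhit = _find_primer(deg, fwd, max_mismatch)
            rhit = _find_primer(deg, rev_rc, max_mismatch)
            if fhit is None or rhit is None:
                continue
            f_end = col_of[fhit[0] + len(fwd) - 1]
            r_start = col_of[rhit[0]]
            if r_start <= f_end:
                continue
            spans.add((f_end + 1, r_start - 1))
        if not spans:
            raise ValueError(
                f"primer pair not located in any reference row at "
                f"<= {max_mismatch} mismatches; consider an explicit column span"
            )
        if len(spans) > 1:
            raise ValueError(
                f"primer pair maps to conflicting column spans across rows: "
                f"{sorted(spans)} — the alignment is inconsistent at the "
                "annealing sites"
            )
        (start, end), = spans
    rows = {sid: s[start - 1 : end] for sid, s in zip(aln.ids, aln.seqs)}
    return RegionSlice(
        start_col=start,
        end_col=end,
        aligned_rows=rows,
        column_map=list(range(start, end + 1)),
    )


# ---------------------------------------------------------------------------
# ASV tables


@dataclass
class AsvTable:
    """ASV sequences plus a sample × ASV integer count matrix."""

    sequences: dict[str, str]  # asv id -> degapped sequence
    counts: pd.DataFrame  # index = samples, columns = asv ids
    parent_taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"ASV {aid!r} has an empty sequence")
            iupac.validate(seq, allow_gaps=False, name=f"ASV {aid!r}")
        missing = set(self.counts.columns) - set(self.sequences)
        if missing:
            raise ValueError(f"count columns without an ASV record: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)


def read_asv_table(
    fasta_path: str | Path,
    counts_path: str | Path,
    parent_taxon: str | Mapping[str, str] = "Cryptophyta",
) -> AsvTable:
    """Read ASV sequences (FASTA) and per-sample counts (TSV, samples as rows)."""
    seqs = {
        rec.id: iupac.normalize(str(rec.seq))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    counts = pd.read_csv(counts_path, sep="\t", index_col=0).astype(np.int64)
    if isinstance(parent_taxon, str):
        parent = {aid: parent_taxon for aid in seqs}
    else:
        parent = dict(parent_taxon)
    return AsvTable(seqs, counts, parent)


def write_asv_table(table: AsvTable, fasta_path: str | Path, counts_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in table.sequences.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta-2line")
    table.counts.to_csv(counts_path, sep="\t", index_label="sample")
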