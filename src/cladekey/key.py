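"""Synapomorphy (diagnostic-character) detection in a clade-labelled alignment.

A region column is diagnostic for a clade when every member of the clade
carries the same unambiguous nucleotide there — a fixed, derived state —
and no sequence outside the clade carries any base compatible with it.
IUPAC codes in outside sequences are expanded conservatively (an N carries
every base, so it blocks every candidate column), whereas any ambiguity or
gap inside the focal clade disqualifies the column outright.  Clades whose
region haplotypes cannot be told apart under this predicate are merged into
a single classification unit (transitively), mirroring sister clades whose
marker subregion is identical.

The predicate is evaluated on a 4-bit base encoding (see :mod:`.iupac`), so
"carries a compatible state" is a vectorised bitwise test across columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import iupac
from .io import CladeMap, ReferenceAlignment, RegionSlice

_UNAMBIG = {1, 2, 4, 8}  # bitmasks of A, C, G, T
_BASE_OF_MASK = {1: "A", 2: "C", 4: "G", 8: "T"}


@dataclass
class ClassificationUnit:
    label: str
    clades: list[str]
    member_ids: list[str]
    diagnostics: list[tuple[int, str]]  # (region column, state)
    representatives: dict[str, str]  # member id -> degapped region sequence
    rep_pos_maps: dict[str, list[int]]  # member id -> degapped pos -> region col


@dataclass
class DiagnosticKey:
    """Per-unit synapomorphies plus the representatives they were called on."""

    units: list[ClassificationUnit]
    region_start: int
    region_end: int
    merged: bool = False

    def unit(self, label: str) -> ClassificationUnit:
        for u in self.units:
            if u.label == label:
                return u
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [u.label for u in self.units]

    def diagnostics_of(self, label: str) -> dict[int, str]:
        return dict(self.unit(label).diagnostics)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region": {"start_col": self.region_start, "end_col": self.region_end},
            "merged": self.merged,
            "units": [
                {
                    "label": u.label,
                    "clades": u.clades,
                    "member_ids": u.member_ids,
                    "diagnostics": [[c, s] for c, s in u.diagnostics],
                    "representatives": u.representatives,
                    "rep_pos_maps": u.rep_pos_maps,
                }
                for u in self.units
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiagnosticKey":
        d = json.loads(Path(path).read_text())
        units = [
            ClassificationUnit(
                label=u["label"],
                clades=u["clades"],
                member_ids=u["member_ids"],
                diagnostics=[(int(c), s) for c, s in u["diagnostics"]],
                representatives=u["representatives"],
                rep_pos_maps={k: list(map(int, v)) for k, v in u["rep_pos_maps"].items()},
            )
            for u in d["units"]
        ]
        return cls(units, d["region"]["start_col"], d["region"]["end_col"], d["merged"])


@dataclass
class PolymorphismCount:
    focal: str
    contrast: list[str]
    scope: str  # "region" | "full"
    count: int
    columns: list[int] = field(default_factory=list)


def _region_matrix(region: RegionSlice, ids: list[str]) -> np.ndarray:
    return np.vstack([iupac.encode(region.aligned_rows[i]) for i in ids])


def _diagnostic_columns(
    masks: np.ndarray, focal_rows: np.ndarray, other_rows: np.ndarray
) -> list[tuple[int, int]]:
    """Columns (0-based) where focal rows are fixed-unambiguous and no other
    row carries a compatible state; returns (column, state-mask) pairs."""
    focal = masks[focal_rows]
    fixed = (focal == focal[0]).all(axis=0) & np.isin(focal[0], list(_UNAMBIG))
    if other_rows.size:
        others = np.bitwise_or.reduce(masks[other_rows], axis=0)
    else:
        others = np.zeros(masks.shape[1], dtype=np.uint8)
    diag = fixed & ((focal[0] & others) == 0)
    return [(j, int(focal[0][j])) for j in np.nonzero(diag)[0]]


def find_diagnostic_columns(region: RegionSlice, clades: CladeMap) -> DiagnosticKey:
    """Pre-merge key: one unit per labelled clade with its diagnostic columns.

    Unlabelled alignment rows are excluded entirely (they neither provide
    diagnostics nor block them).
    """
    if region.width == 0:
        raise ValueError("empty region")
    labeled = [i for i in region.aligned_rows if i in clades.assignments]
    if not labeled:
        raise ValueError("no labelled sequences in the region")
    masks = _region_matrix(region, labeled)
    row_of = {sid: k for k, sid in enumerate(labeled)}
    units = []
    for clade in clades.clades:
        members = [m for m in clades.members(clade) if m in row_of]
        if not members:
            raise ValueError(f"clade {clade!r} has no members in the region")
        focal_rows = np.array([row_of[m] for m in members])
        other_rows = np.array(
            [k for sid, k in row_of.items() if clades.assignments[sid] != clade],
            dtype=int,
        )
        diags = [
            (region.column_map[j], _BASE_OF_MASK[m])
            for j, m in _diagnostic_columns(masks, focal_rows, other_rows)
        ]
        units.append(
            ClassificationUnit(
                label=clade,
                clades=[clade],
                member_ids=members,
                diagnostics=diags,
                representatives={m: region.degapped[m] for m in members},
                rep_pos_maps={
                    m: [region.column_map[k - 1] for k in region.pos_maps[m]]
                    for m in members
                },
            )
        )
    return DiagnosticKey(units, region.start_col, region.end_col, merged=False)


def _pairwise_indistinguishable(
    masks: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray
) -> bool:
    """True when no column is diagnostic for A against B nor B against A."""
    return not _diagnostic_columns(masks, rows_a, rows_b) and not _diagnostic_columns(
        masks, rows_b, rows_a
    )


def merge_indistinguishable(
    key: DiagnosticKey, region: RegionSlice, clades: CladeMap
) -> DiagnosticKey:
    """Merge clades the region cannot separate into joint units ("A/B").

    Two clades merge when neither has a diagnostic column against the other
    alone; merging is the transitive closure of that relation, so the result
    is independent of clade input order.  Unit diagnostics are recomputed
    against all non-member clades after merging.
    """
    labeled = [i for i in region.aligned_rows if i in clades.assignments]
    masks = _region_matrix(region, labeled)
    row_of = {sid: k for k, sid in enumerate(labeled)}
    clade_rows = {
        c: np.array([row_of[m] for m in clades.members(c) if m in row_of])
        for c in clades.clades
    }
    order = sorted(clade_rows)
    parent = {c: c for c in order}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in combinations(order, 2):
        if find(a) != find(b) and _pairwise_indistinguishable(
            masks, clade_rows[a], clade_rows[b]
        ):
            parent[find(b)] = find(a)

    groups: dict[str, list[str]] = {}
    for c in order:
        groups.setdefault(find(c), []).append(c)
    # keep original clade-map ordering inside and across units
    clade_order = {c: k for k, c in enumerate(clades.clades)}
    merged_units = []
    for group in sorted(groups.values(), key=lambda g: min(clade_order[c] for c in g)):
        group = sorted(group)  # canonical label, independent of input order
        members = [m for c in group for m in clades.members(c) if m in row_of]
        focal_rows = np.concatenate([clade_rows[c] for c in group])
        other_rows = np.array(
            [k for sid, k in row_of.items() if clades.assignments[sid] not in group],
            dtype=int,
        )
        diags = [
            (region.column_map[j], _BASE_OF_MASK[m])
            for j, m in _diagnostic_columns(masks, focal_rows, other_rows)
        ]
        merged_units.append(
            ClassificationUnit(
                label="/".join(group),
                clades=group,
                member_ids=members,
                diagnostics=diags,
                representatives={m: region.degapped[m] for m in members},
                rep_pos_maps={
                    m: [region.column_map[k - 1] for k in region.pos_maps[m]]
                    for m in members
                },
            )
        )
    if len(merged_units) == 1 and len(order) > 1:
        import warnings

        warnings.warn(
            "all clades merged into a single unit: the region carries no "
            "distinguishing states",
            stacklevel=2,
        )
    return DiagnosticKey(merged_units, key.region_start, key.region_end, merged=True)


def build_key(region: RegionSlice, clades: CladeMap) -> DiagnosticKey:
    """Detect diagnostics and merge indistinguishable clades in one step."""
    return merge_indistinguishable(find_diagnostic_columns(region, clades), region, clades)


def count_clade_polymorphisms(
    aln: ReferenceAlignment,
    clades: CladeMap,
    focal: str,
    contrast: list[str],
    scope: str = "full",
    region: RegionSlice | None = None,
) -> PolymorphismCount:
    """Count columns where the focal clade is fixed for a state that no
    contrast-clade sequence carries (the same predicate as key detection,
    with the outgroup restricted to the given contrast set).
    """
    contrast = list(contrast)
    if not contrast or focal in contrast:
        raise ValueError("contrast set must be non-empty and disjoint from focal")
    if scope == "region":
        if region is None:
            raise ValueError("scope='region' requires a RegionSlice")
        rows = {sid: region.aligned_rows[sid] for sid in region.aligned_rows}
        col_of = region.column_map
    elif scope == "full":
        rows = dict(zip(aln.ids, aln.seqs))
        col_of = list(range(1, aln.length + 1))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    focal_ids = clades.members(focal)
    contrast_ids = [m for c in contrast for m in clades.members(c)]
    if not focal_ids or not contrast_ids:
        raise ValueError("focal and contrast clades must be non-empty")
    masks = np.vstack([iupac.encode(rows[i]) for i in focal_ids + contrast_ids])
    nf = len(focal_ids)
    hits = _diagnostic_columns(masks, np.arange(nf), np.arange(nf, masks.shape[0]))
    cols = [col_of[j] for j, _ in hits]
    return PolymorphismCount(focal, contrast, scope, len(cols), cols)


# ---------------------------------------------------------------------------
# within-clade identity


@dataclass
class CladeIdentity:
    clade: str
    n_haplotypes: int
    max_pairwise_diff: int
    haplotypes: list[str]


def _pair_diff(a: str, b: str) -> int:
    """Substitution distance between two degapped haplotypes.

    Hamming for equal lengths; otherwise the mismatch count of the
    semi-global alignment (terminal overhangs excluded).
    """
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if not iupac.compatible(x, y))
    from .pairwise import semiglobal_align

    res = semiglobal_align(a, b)
    return res.columns - res.matches


def validate_within_clade(region: RegionSlice, clades: CladeMap) -> pd.DataFrame:
    """Per-clade distinct region haplotypes and maximum pairwise distance.

    A clade with a single haplotype is 100% identical within itself for the
    region; multi-haplotype clades are the analogue of reference clades
    carrying 1-nt variants.
    """
    rows = []
    for clade in clades.clades:
        haps: list[str] = []
        for m in clades.members(clade):
            h = region.degapped[m]
            if h not in haps:
                haps.append(h)
        maxd = max(
            (_pair_diff(a, b) for a, b in combinations(haps, 2)), default=0
        )
        rows.append(
            CladeIdentity(clade, len(haps), maxd, haps)
        )
    return pd.DataFrame(
        {
            "clade": [r.clade for r in rows],
            "n_haplotypes": [r.n_haplotypes for r in rows],
            "max_pairwise_diff": [r.max_pairwise_diff for r in rows],
            "haplotypes": [";".join(r.haplotypes) for r in rows],
        }
    )
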