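"""Clade relative-abundance tables and per-sample diversity metrics.

Relative abundances are computed within a parent taxon's amplicons per
sample (the denominator keeps unclassified and ambiguous reads), and a
per-sample read-count threshold τ turns raw unit counts into a detected /
not-detected flag — a unit with fewer than τ reads in a sample is reported
as not detected, though its computed abundance is retained.

Diversity follows the standard formulas: richness S is the number of taxa
with positive counts, Shannon H = −Σ p_i ln p_i, and rarefaction is the
exact hypergeometric expectation E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d)),
evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import AsvTable

DEFAULT_TAU = 10


@dataclass
class CladeAbundanceTable:
    """Tidy per-sample × per-unit reads/abundance/detection table."""

    table: pd.DataFrame  # sample, unit, reads, rel_abund, detected, parent_total
    tau: int
    parent: str

    def sample_totals(self) -> pd.Series:
        return self.table.groupby("sample")["parent_total"].first()

    def detected_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="sample", columns="unit", values="detected")

    def abundance_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="sample", columns="unit", values="rel_abund")


def clade_abundance(
    asvs: AsvTable,
    assign: pd.DataFrame,
    parent: str = "Cryptophyta",
    tau: int = DEFAULT_TAU,
) -> CladeAbundanceTable:
    """Aggregate ASV counts into unit reads and thresholded relative abundances.

    ``assign`` is the per-ASV classification frame; ASVs classified as
    "unclassified"/"ambiguous" contribute to the parent-taxon denominator
    but to no unit.  Samples with zero parent reads carry NaN abundances
    (flagged, never a division error).
    """
    if parent not in set(asvs.parent_taxon.values()):
        raise ValueError(f"parent taxon {parent!r} absent from ASV annotations")
    missing = set(asvs.asv_ids) - set(assign["asv_id"])
    if missing:
        raise ValueError(f"ASVs without an assignment outcome: {sorted(missing)[:5]}")
    unit_of = dict(zip(assign["asv_id"], assign["unit"]))
    parent_ids = [a for a in asvs.asv_ids if asvs.parent_taxon.get(a) == parent]
    counts = asvs.counts[parent_ids]
    units = sorted(
        {u for u in unit_of.values() if u not in ("unclassified", "ambiguous")}
    )
    parent_total = counts.sum(axis=1)
    rows = []
    for unit in units:
        ids = [a for a in parent_ids if unit_of[a] == unit]
        reads = counts[ids].sum(axis=1) if ids else pd.Series(0, index=counts.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(parent_total > 0, reads / parent_total, np.nan)
        for sample, r, ra, pt in zip(counts.index, reads, rel, parent_total):
            rows.append((sample, unit, int(r), ra, int(r) >= tau, int(pt)))
    table = pd.DataFrame(
        rows, columns=["sample", "unit", "reads", "rel_abund", "detected", "parent_total"]
    )
    return CladeAbundanceTable(table, tau=tau, parent=parent)


def shannon_richness(counts) -> tuple[int, float]:
    """Richness S and Shannon H (natural log) of one count vector.

    An all-zero vector yields (0, nan) rather than an exception.
    """
    n = np.asarray(counts, dtype=float)
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    pos = n[n > 0]
    s = int(pos.size)
    if s == 0:
        return 0, float("nan")
    p = pos / pos.sum()
    return s, float(-(p * np.log(p)).sum())


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness and Shannon H over a sample × taxon count matrix."""
    rows = []
    for sample in counts.index:
        s, h = shannon_richness(counts.loc[sample].to_numpy())
        rows.append((sample, s, h))
    return pd.DataFrame(rows, columns=["sample", "richness", "shannon"])


def rarefaction(counts, depths) -> np.ndarray:
    """Exact expected richness at each subsampling depth.

    E[S_d] = Σ_i [1 − C(N−n_i, d)/C(N, d)], the mean richness over all
    without-replacement subsamples of d reads; computed with log-gamma for
    stability.  Depths beyond the sample total are an error.
    """
    n = np.asarray(counts, dtype=np.int64)
    n = n[n > 0]
    N = int(n.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths < 0).any() or (depths > N).any():
        raise ValueError(f"depths must lie in [0, {N}]")
    # log C(N-n_i, d) - log C(N, d) with the convention C(a, d)=0 for a < d
    out = np.empty(depths.shape, dtype=float)
    for k, d in enumerate(depths):
        keep = (N - n) >= d
        log_absent = np.full(n.shape, -np.inf)
        if d == 0:
            log_absent[:] = 0.0
        else:
            a = (N - n)[keep]
            log_absent[keep] = (
                gammaln(a + 1)
                - gammaln(d + 1)
                - gammaln(a - d + 1)
                - (gammaln(N + 1) - gammaln(d + 1) - gammaln(N - d + 1))
            )
        out[k] = float(np.sum(1.0 - np.exp(log_absent)))
    return out


def rarefaction_table(counts: pd.DataFrame, depths) -> pd.DataFrame:
    """Rarefaction curves for every row of a sample × taxon count matrix,
    evaluated at the requested depths clipped to each sample's total."""
    rows = []
    for sample in counts.index:
        vec = counts.loc[sample].to_numpy()
        total = int(vec.sum())
        dd = [d for d in depths if d <= total]
        for d, es in zip(dd, rarefaction(vec, dd)):
            rows.append((sample, int(d), es))
    return pd.DataFrame(rows, columns=["sample", "depth", "expected_richness"])
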