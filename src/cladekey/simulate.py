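"""Synthetic marker-gene survey generator with recorded ground truth.

The generator emulates the statistical structure of a clade-resolved
amplicon survey of a single algal parent taxon:

* a clade-structured reference alignment over a full-length marker gene,
  with clade-specific substitutions planted at known columns inside a V9-
  like subregion (the true synapomorphies), amplification primers planted
  flanking the subregion, and perfect within-clade sequence identity except
  for designated "variant" clades that carry three 1-nt-distinct haplotypes;
* per-station ASV tables drawn multinomially from latitude-structured clade
  compositions — every clade has a Gaussian latitudinal niche on top of a
  uniform baseline except one planted south-endemic clade that is absent
  north of the Antarctic band — with optional per-base substitution errors;
* flow-cytometry-style cell counts with a planted log-linear positive
  temperature effect, plus station environment tables.

Every artifact draws from its own pseudo-random stream derived from the
master seed by a fixed offset, so regenerating one stage never perturbs
the others; outputs are byte-identical across runs for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import iupac
from .ecology import CytometryRecord, StationRecord, DEFAULT_BAND_EDGES
from .io import (
    AsvTable,
    CladeMap,
    ReferenceAlignment,
    write_alignment,
    write_asv_table,
    write_clade_map,
)

_BASES = np.array(list("ACGT"))

_ROMAN = [
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass
class SimConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror the structure of the motivating field study: nine
    clades in the reference lineage, a ~130-column marker subregion inside
    a 1,649-column gene alignment, a ~2/9 chance that a clade carries three
    1-nt variant haplotypes, one Antarctic-endemic clade (the seventh,
    "VII"), a detection threshold of 10 reads, and a positive temperature
    effect on cell abundance.  Sequencing error defaults to zero because
    field inputs are denoised ASVs; a nonzero per-base substitution rate
    models residual error.
    """

    seed: int = 0
    # reference alignment
    n_clades: int = 9
    members_per_clade: tuple[int, int] = (2, 6)
    gene_length: int = 1649
    region_span: tuple[int, int] = (1480, 1609)
    diagnostics_per_clade: tuple[int, int] = (2, 4)
    extra_gene_diagnostics: tuple[int, int] = (0, 0)  # planted outside the region
    variant_clade_prob: float = 2.0 / 9.0
    fwd_primer: str = "TTGTACACACCGCCC"
    rev_primer: str = "CCTTCYGCAGGTTCACCTAC"
    # survey
    n_stations: int = 25
    depth_range: tuple[int, int] = (2000, 20000)
    error_rate: float = 0.0
    endemic_clade_index: int | None = 6  # 0-based; clade "VII" by default
    endemic_cutoff_lat: float = -60.0
    endemic_weight: float = 3.0
    baseline_weight: float = 0.25
    niche_width: float = 30.0
    tau: int = 10
    # environment / cytometry
    n_profiles: int = 42
    cyto_temp_range: tuple[float, float] = (-1.8, 2.0)
    log_abundance_intercept: float = 7.5
    temp_slope: float = 0.8
    log_noise_sd: float = 0.35

    def __post_init__(self) -> None:
        rs, re = self.region_span
        if not (1 <= rs <= re <= self.gene_length):
            raise ValueError("region span must lie inside the gene")
        if rs - 1 < len(self.fwd_primer) or re + len(self.rev_primer) > self.gene_length:
            raise ValueError("no room to plant primers flanking the region")
        if not (0.0 <= self.variant_clade_prob <= 1.0 and 0.0 <= self.error_rate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_clades < 1 or self.members_per_clade[0] < 1:
            raise ValueError("counts must be positive")

    def clade_labels(self) -> list[str]:
        return [roman(i + 1) for i in range(self.n_clades)]

    @property
    def endemic_clade(self) -> str | None:
        i = self.endemic_clade_index
        if i is None or not (0 <= i < self.n_clades):
            return None
        return roman(i + 1)


@dataclass
class SurveyTruth:
    """Generator-side ground truth for recovery tests."""

    diagnostics: dict[str, dict[int, str]]  # clade -> {alignment column: state}
    gene_diagnostics: dict[str, dict[int, str]]  # incl. planted outside region
    variant_clades: list[str]
    haplotypes: dict[str, list[str]]  # clade -> degapped region haplotypes
    endemic_clade: str | None = None
    compositions: pd.DataFrame | None = None  # station × clade true fractions
    temp_slope: float | None = None
    config: SimConfig | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "diagnostics": {c: {str(k): v for k, v in d.items()} for c, d in self.diagnostics.items()},
            "gene_diagnostics": {c: {str(k): v for k, v in d.items()} for c, d in self.gene_diagnostics.items()},
            "variant_clades": self.variant_clades,
            "haplotypes": self.haplotypes,
            "endemic_clade": self.endemic_clade,
            "compositions": (
                None if self.compositions is None
                else {s: {c: round(float(v), 10) for c, v in row.items()}
                      for s, row in self.compositions.iterrows()}
            ),
            "temp_slope": self.temp_slope,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _resolve(seq: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC ambiguity codes to concrete bases (for planting)."""
    out = []
    for c in iupac.normalize(seq):
        exp = [b for b in "ACGT" if iupac.MASK[c] & iupac.MASK[b]]
        out.append(exp[0] if len(exp) == 1 else str(rng.choice(exp)))
    return "".join(out)


def simulate_reference_set(
    cfg: SimConfig,
) -> tuple[ReferenceAlignment, CladeMap, SurveyTruth]:
    """Generate the clade-labelled reference alignment with planted truth."""
    rng = _rng(cfg, 0)
    L = cfg.gene_length
    rs, re = cfg.region_span
    gene = rng.choice(_BASES, size=L)
    fwd = _resolve(cfg.fwd_primer, rng)
    rev_rc = _resolve(iupac.reverse_complement(cfg.rev_primer), rng)
    gene[rs - 1 - len(fwd) : rs - 1] = list(fwd)
    gene[re : re + len(rev_rc)] = list(rev_rc)

    labels = cfg.clade_labels()
    n_members = rng.integers(
        cfg.members_per_clade[0], cfg.members_per_clade[1] + 1, size=cfg.n_clades
    )
    k_diag = rng.integers(
        cfg.diagnostics_per_clade[0], cfg.diagnostics_per_clade[1] + 1,
        size=cfg.n_clades,
    )
    k_extra = rng.integers(
        cfg.extra_gene_diagnostics[0], cfg.extra_gene_diagnostics[1] + 1,
        size=cfg.n_clades,
    )
    variant = np.array(
        [
            (rng.random() < cfg.variant_clade_prob) and n_members[i] >= 3
            for i in range(cfg.n_clades)
        ]
    )
    region_cols = np.arange(rs, re + 1)
    need = int(k_diag.sum() + 2 * variant.sum())
    if need > region_cols.size:
        raise ValueError(
            f"requested {need} planted columns exceed the {region_cols.size} "
            "available region columns"
        )
    picked = rng.choice(region_cols, size=need, replace=False)
    outside_cols = np.concatenate(
        [np.arange(1, rs - len(fwd)), np.arange(re + len(rev_rc) + 1, L + 1)]
    )
    n_extra = int(k_extra.sum())
    if n_extra > outside_cols.size:
        raise ValueError("requested outside-region columns exceed availability")
    picked_out = rng.choice(outside_cols, size=n_extra, replace=False) if n_extra else np.array([], dtype=int)

    diagnostics: dict[str, dict[int, str]] = {}
    gene_diagnostics: dict[str, dict[int, str]] = {}
    variant_cols: dict[str, list[int]] = {}
    p = q = 0
    for i, lab in enumerate(labels):
        cols = picked[p : p + k_diag[i]]
        p += k_diag[i]
        diag = {}
        for col in cols:
            anc = gene[col - 1]
            diag[int(col)] = str(rng.choice([b for b in "ACGT" if b != anc]))
        diagnostics[lab] = dict(sorted(diag.items()))
        out_diag = {}
        for col in picked_out[q : q + k_extra[i]]:
            anc = gene[col - 1]
            out_diag[int(col)] = str(rng.choice([b for b in "ACGT" if b != anc]))
        q += k_extra[i]
        gene_diagnostics[lab] = dict(sorted({**diag, **out_diag}.items()))
        if variant[i]:
            variant_cols[lab] = [int(c) for c in picked[p : p + 2]]
            p += 2

    ids, seqs, assignments = [], [], {}
    haplotypes: dict[str, list[str]] = {}
    for i, lab in enumerate(labels):
        base = gene.copy()
        for col, state in gene_diagnostics[lab].items():
            base[col - 1] = state
        haps = []
        for j in range(int(n_members[i])):
            member = base.copy()
            if lab in variant_cols and 1 <= j <= 2:
                col = variant_cols[lab][j - 1]
                cur = member[col - 1]
                member[col - 1] = rng.choice([b for b in "ACGT" if b != cur])
            sid = f"{lab}_{j + 1}"
            ids.append(sid)
            seqs.append("".join(member))
            assignments[sid] = lab
            region_hap = "".join(member[rs - 1 : re])
            if region_hap not in haps:
                haps.append(region_hap)
        haplotypes[lab] = haps

    truth = SurveyTruth(
        diagnostics=diagnostics,
        gene_diagnostics=gene_diagnostics,
        variant_clades=[labels[i] for i in range(cfg.n_clades) if variant[i]],
        haplotypes=haplotypes,
        endemic_clade=cfg.endemic_clade,
        temp_slope=cfg.temp_slope,
        config=cfg,
    )
    return ReferenceAlignment(ids, seqs), CladeMap(assignments), truth


# ---------------------------------------------------------------------------
# survey


def _station_latitudes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Latitudes cycling through the five default bands, jittered within."""
    edges = DEFAULT_BAND_EDGES
    lats = np.empty(cfg.n_stations)
    for i in range(cfg.n_stations):
        b = i % (len(edges) - 1)
        lo, hi = edges[b], edges[b + 1]
        lo, hi = lo + 2.0, hi - 2.0  # keep clear of band boundaries
        lats[i] = rng.uniform(lo, hi)
    return lats


def true_compositions(cfg: SimConfig, lats: np.ndarray) -> pd.DataFrame:
    """Deterministic niche-model clade fractions for the given latitudes."""
    labels = cfg.clade_labels()
    endemic = cfg.endemic_clade
    others = [c for c in labels if c != endemic]
    centers = dict(zip(others, np.linspace(-75, 75, len(others)))) if others else {}
    rows = []
    for lat in lats:
        w = {}
        for c in labels:
            if c == endemic:
                w[c] = cfg.endemic_weight if lat <= cfg.endemic_cutoff_lat else 0.0
            else:
                w[c] = cfg.baseline_weight + float(
                    np.exp(-((lat - centers[c]) ** 2) / (2 * cfg.niche_width**2))
                )
        total = sum(w.values())
        rows.append({c: w[c] / total for c in labels})
    stations = [f"S{i + 1:02d}" for i in range(len(lats))]
    return pd.DataFrame(rows, index=stations)


def per_read_error_probability(error_rate: float, length: int) -> float:
    """Probability that a read of the given length carries ≥1 substitution."""
    return 1.0 - (1.0 - error_rate) ** length


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=k, replace=False)
    for p in pos:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


def simulate_survey(
    cfg: SimConfig, truth: SurveyTruth
) -> tuple[AsvTable, list[StationRecord]]:
    """Draw per-station ASV tables from the niche model plus the error model.

    Reads are drawn multinomially at each station's depth from the true
    clade composition; each read takes one of its clade's region haplotypes
    (uniformly for variant clades) and, at a nonzero error rate, a
    binomially distributed number of substitution errors.
    """
    rng = _rng(cfg, 1)
    lats = _station_latitudes(cfg, rng)
    comps = true_compositions(cfg, lats)
    truth.compositions = comps
    labels = cfg.clade_labels()
    stations = list(comps.index)

    seq_counts: dict[str, dict[str, int]] = {}

    def add(station: str, seq: str, n: int) -> None:
        if n:
            seq_counts.setdefault(seq, dict()).setdefault(station, 0)
            seq_counts[seq][station] += n

    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=len(stations))
    for st, depth in zip(stations, depths):
        clade_counts = rng.multinomial(depth, comps.loc[st, labels].to_numpy())
        for lab, n in zip(labels, clade_counts):
            if n == 0:
                continue
            haps = truth.haplotypes[lab]
            hap_counts = rng.multinomial(n, np.full(len(haps), 1.0 / len(haps)))
            for hap, hn in zip(haps, hap_counts):
                hn = int(hn)
                if hn == 0:
                    continue
                if cfg.error_rate > 0:
                    p_err = per_read_error_probability(cfg.error_rate, len(hap))
                    n_err = int(rng.binomial(hn, p_err))
                    add(st, hap, hn - n_err)
                    for _ in range(n_err):
                        k = 0
                        while k == 0:
                            k = int(rng.binomial(len(hap), cfg.error_rate))
                        add(st, _mutate(hap, k, rng), 1)
                else:
                    add(st, hap, hn)

    # stable ASV ids: by total count descending, then sequence
    order = sorted(
        seq_counts, key=lambda s: (-sum(seq_counts[s].values()), s)
    )
    ids = {seq: f"asv_{i + 1:05d}" for i, seq in enumerate(order)}
    counts = pd.DataFrame(
        0, index=stations, columns=[ids[s] for s in order], dtype=np.int64
    )
    sequences = {}
    for seq in order:
        aid = ids[seq]
        sequences[aid] = seq
        for st, n in seq_counts[seq].items():
            counts.loc[st, aid] = n
    table = AsvTable(sequences, counts, {a: "Cryptophyta" for a in sequences})

    recs = []
    for st, lat in zip(stations, lats):
        temp = 28.0 - 0.42 * abs(lat) + rng.normal(0.0, 1.0)
        chla = float(np.exp(rng.normal(-0.5, 0.8)))
        recs.append(
            StationRecord(
                station=st,
                latitude=float(lat),
                longitude=float(rng.uniform(-180, 180)),
                region="simulated",
                covariates={"temperature": float(temp), "chl_a": chla},
            )
        )
    return table, recs


def simulate_cyto_env(
    cfg: SimConfig,
) -> tuple[list[CytometryRecord], list[StationRecord]]:
    """Cell counts with a planted log-linear temperature effect.

    cryptophyte cells·mL⁻¹ = exp(a + b·T + ε), ε ~ N(0, σ²); other
    photosynthetic cells are drawn independently of temperature, so the
    planted effect is specific to the focal group.
    """
    rng = _rng(cfg, 2)
    cyto, recs = [], []
    for i in range(cfg.n_profiles):
        st = f"P{i + 1:02d}"
        temp = float(rng.uniform(*cfg.cyto_temp_range))
        crypto = float(
            np.exp(
                cfg.log_abundance_intercept
                + cfg.temp_slope * temp
                + rng.normal(0.0, cfg.log_noise_sd)
            )
        )
        noncrypto = float(np.exp(7.8 + rng.normal(0.0, 0.4)))
        total = crypto + noncrypto
        depth = float(rng.choice([1.5, 10.0, 25.0, 50.0]))
        chla = total * 8e-5 * float(np.exp(rng.normal(0.0, 0.2)))
        cyto.append(CytometryRecord(st, depth, total, crypto))
        recs.append(
            StationRecord(
                station=st,
                latitude=-64.85 + float(rng.normal(0.0, 0.05)),
                longitude=-62.6 + float(rng.normal(0.0, 0.05)),
                region="fjord",
                covariates={"temperature": temp, "chl_a": chla},
            )
        )
    return cyto, recs


# ---------------------------------------------------------------------------
# file output


def write_survey(
    outdir: str | Path,
    aln: ReferenceAlignment,
    clades: CladeMap,
    asvs: AsvTable,
    stations: list[StationRecord],
    cyto: list[CytometryRecord] | None = None,
    cyto_stations: list[StationRecord] | None = None,
    truth: SurveyTruth | None = None,
) -> None:
    """Write every artifact in the same text formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_alignment(aln, out / "reference.afa")
    write_clade_map(clades, out / "clades.tsv")
    write_asv_table(asvs, out / "asvs.fasta", out / "counts.tsv")
    _station_tsv(stations).to_csv(out / "stations.tsv", sep="\t", index=False)
    if cyto is not None:
        pd.DataFrame(
            {
                "station": [c.station for c in cyto],
                "depth_m": [c.depth_m for c in cyto],
                "total_cells_per_ml": [round(c.total_cells_per_ml, 3) for c in cyto],
                "crypto_cells_per_ml": [round(c.crypto_cells_per_ml, 3) for c in cyto],
            }
        ).to_csv(out / "cytometry.tsv", sep="\t", index=False)
    if cyto_stations is not None:
        _station_tsv(cyto_stations).to_csv(out / "cyto_stations.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_json(out / "truth.json")


def _station_tsv(stations: list[StationRecord]) -> pd.DataFrame:
    cov_keys: list[str] = []
    for s in stations:
        for k in s.covariates:
            if k not in cov_keys:
                cov_keys.append(k)
    rows = []
    for s in stations:
        row = {
            "station": s.station,
            "latitude": round(s.latitude, 6),
            "longitude": None if s.longitude is None else round(s.longitude, 6),
            "region": s.region,
        }
        row.update({k: round(s.covariates[k], 6) for k in cov_keys if k in s.covariates})
        rows.append(row)
    return pd.DataFrame(rows)
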