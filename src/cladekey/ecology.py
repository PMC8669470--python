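"""Biogeography, environment correlations and quantitative conversions.

Endemism is judged against latitude bands (default: Antarctic south of
−60°, south-temperate, tropical, north-temperate, Arctic north of 60°):
a unit is endemic to a band when it is detected in that band and nowhere
else across the survey.  Environment–taxon associations use Pearson
product-moment correlations with Bonferroni adjustment over all pairs
tested in the call.  Cell counts convert to carbon via geometric cell
volumes (prolate spheroid for the measured cryptophyte, sphere for other
phytoplankton) times a carbon:volume ratio, and qPCR well counts convert
to gene copies per mL of seawater from the run's volumes and dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: band edges (ascending) and the names of the intervals between them
DEFAULT_BAND_EDGES = [-90.0, -60.0, -23.5, 23.5, 60.0, 90.0]
DEFAULT_BAND_NAMES = [
    "antarctic",
    "south_temperate",
    "tropical",
    "north_temperate",
    "arctic",
]


@dataclass
class StationRecord:
    station: str
    latitude: float
    longitude: float | None = None
    region: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValueError(f"station {self.station!r}: |latitude| > 90")


@dataclass
class CytometryRecord:
    station: str
    depth_m: float
    total_cells_per_ml: float
    crypto_cells_per_ml: float

    def __post_init__(self) -> None:
        if not (0 <= self.crypto_cells_per_ml <= self.total_cells_per_ml):
            raise ValueError(
                f"{self.station!r}: cryptophyte count outside [0, total]"
            )


def load_stations(path: str | Path) -> list[StationRecord]:
    """Read a station metadata TSV (station, latitude, longitude, region,
    plus any numeric covariate columns; missing values allowed)."""
    df = pd.read_csv(path, sep="\t")
    core = {"station", "latitude", "longitude", "region"}
    recs = []
    for _, r in df.iterrows():
        cov = {
            c: float(r[c])
            for c in df.columns
            if c not in core and pd.notna(r[c])
        }
        recs.append(
            StationRecord(
                station=str(r["station"]),
                latitude=float(r["latitude"]),
                longitude=float(r["longitude"]) if "longitude" in df and pd.notna(r.get("longitude")) else None,
                region=str(r["region"]) if "region" in df and pd.notna(r.get("region")) else None,
                covariates=cov,
            )
        )
    return recs


def stations_frame(stations: list[StationRecord]) -> pd.DataFrame:
    rows = []
    for s in stations:
        row = {"station": s.station, "latitude": s.latitude}
        row.update(s.covariates)
        rows.append(row)
    return pd.DataFrame(rows).set_index("station")


# ---------------------------------------------------------------------------
# endemism / biogeography


def band_of(lat: float, edges=DEFAULT_BAND_EDGES, names=DEFAULT_BAND_NAMES) -> str:
    for lo, hi, name in zip(edges[:-1], edges[1:], names):
        if lo <= lat < hi or (hi == edges[-1] and lat == hi):
            return name
    raise ValueError(f"latitude {lat} outside bands")


def endemism_summary(
    abund,
    stations: list[StationRecord],
    sample_station: dict[str, str] | None = None,
    band_edges=DEFAULT_BAND_EDGES,
    band_names=DEFAULT_BAND_NAMES,
) -> pd.DataFrame:
    """Per-unit detection range, per-band detection frequency and endemism.

    ``abund`` is a CladeAbundanceTable; ``sample_station`` maps sample ids
    to station ids (identity by default).  A unit is endemic to a band when
    its detected stations fall in that band and in no other.
    """
    station_lat = {s.station: s.latitude for s in stations}
    table = abund.table
    samples = table["sample"].unique()
    sample_station = sample_station or {s: s for s in samples}
    missing = [s for s in samples if sample_station.get(s) not in station_lat]
    if missing:
        raise ValueError(f"samples with no station record: {missing}")
    lat_of = {s: station_lat[sample_station[s]] for s in samples}
    band_of_sample = {
        s: band_of(lat_of[s], band_edges, band_names) for s in samples
    }
    band_stations = {
        b: {sample_station[s] for s in samples if band_of_sample[s] == b}
        for b in band_names
    }
    rows = []
    for unit, sub in table.groupby("unit", sort=True):
        det = sub[sub["detected"]]
        det_stations = sorted({sample_station[s] for s in det["sample"]})
        lats = [station_lat[st] for st in det_stations]
        det_bands = {band_of_sample[s] for s in det["sample"]}
        freq = {}
        share = {}
        for b in band_names:
            in_band = sub[[band_of_sample[s] == b for s in sub["sample"]]]
            n_st = len(band_stations[b])
            det_st = {sample_station[s] for s in in_band[in_band["detected"]]["sample"]}
            freq[b] = len(det_st) / n_st if n_st else np.nan
            share[b] = float(in_band["rel_abund"].mean()) if len(in_band) else np.nan
        endemic_band = next(iter(det_bands)) if len(det_bands) == 1 else None
        row = {
            "unit": unit,
            "n_detected_stations": len(det_stations),
            "min_lat": min(lats) if lats else np.nan,
            "max_lat": max(lats) if lats else np.nan,
            "endemic_band": endemic_band,
        }
        row.update({f"freq_{b}": freq[b] for b in band_names})
        row.update({f"share_{b}": share[b] for b in band_names})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations


def pearson_bonferroni(
    x: pd.DataFrame, y: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r with Bonferroni-adjusted p for every (x column, y column) pair.

    Missing values are deleted pairwise; pairs with fewer than 3 complete
    observations or zero variance yield NaN r (flagged, still counted in
    the family size m = number of pairs in the call).  p comes from the
    t-transform with n−2 degrees of freedom; p_adj = min(1, m·p).
    """
    x = x.apply(pd.to_numeric)
    y = y.apply(pd.to_numeric)
    pairs = [(cx, cy) for cx in x.columns for cy in y.columns]
    m = len(pairs)
    rows = []
    for cx, cy in pairs:
        xv = x[cx].to_numpy(dtype=float)
        yv = y[cy].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        n = int(ok.sum())
        r = p = np.nan
        if n >= 3:
            xs, ys = xv[ok], yv[ok]
            sx, sy = xs.std(), ys.std()
            if sx > 0 and sy > 0:
                r = float(np.corrcoef(xs, ys)[0, 1])
                r = max(-1.0, min(1.0, r))
                if abs(r) == 1.0:
                    p = 0.0
                else:
                    t = r * math.sqrt((n - 2) / (1 - r * r))
                    p = float(2 * stats.t.sf(abs(t), df=n - 2))
        p_adj = min(1.0, m * p) if np.isfinite(p) else np.nan
        rows.append(
            {
                "x": cx, "y": cy, "n": n, "r": r,
                "p_raw": p, "p_adj": p_adj, "m": m,
                "significant": bool(np.isfinite(p_adj) and p_adj <= alpha),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# biomass and qPCR conversions


@dataclass
class BiomassParams:
    """Cell-geometry and carbon-conversion parameters.

    The cryptophyte is modelled as a prolate spheroid from measured length
    and width (defaults: the study population's 11.3 × 5.1 μm means); other
    phytoplankton as 5.5-μm spheres at 237 fg C·μm⁻³.  The cryptophyte
    carbon:volume ratio has no default and must be supplied from the
    literature source chosen by the user.
    """

    crypto_length_um: float = 11.3
    crypto_width_um: float = 5.1
    crypto_fgC_per_um3: float | None = None
    noncrypto_diameter_um: float = 5.5
    noncrypto_fgC_per_um3: float = 237.0

    def __post_init__(self) -> None:
        for name in (
            "crypto_length_um", "crypto_width_um",
            "noncrypto_diameter_um", "noncrypto_fgC_per_um3",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.crypto_fgC_per_um3 is not None and self.crypto_fgC_per_um3 <= 0:
            raise ValueError("crypto_fgC_per_um3 must be positive")

    @property
    def crypto_volume_um3(self) -> float:
        return math.pi / 6.0 * self.crypto_length_um * self.crypto_width_um**2

    @property
    def noncrypto_volume_um3(self) -> float:
        return math.pi / 6.0 * self.noncrypto_diameter_um**3


def biomass(cyto: CytometryRecord, params: BiomassParams) -> dict[str, float]:
    """Carbon per mL (fg C·mL⁻¹) for cryptophytes, other phytoplankton, total."""
    if params.crypto_fgC_per_um3 is None:
        raise ValueError(
            "BiomassParams.crypto_fgC_per_um3 is required: supply a "
            "cryptophyte carbon:volume ratio (fg C per μm³) from the "
            "literature source of your choice"
        )
    crypto = (
        cyto.crypto_cells_per_ml * params.crypto_volume_um3 * params.crypto_fgC_per_um3
    )
    noncrypto = (
        (cyto.total_cells_per_ml - cyto.crypto_cells_per_ml)
        * params.noncrypto_volume_um3
        * params.noncrypto_fgC_per_um3
    )
    return {
        "crypto_fgC_per_ml": crypto,
        "noncrypto_fgC_per_ml": noncrypto,
        "total_fgC_per_ml": crypto + noncrypto,
    }


@dataclass
class QpcrRun:
    """One qPCR measurement traced back to seawater volume."""

    copies_per_well: float
    template_volume_ul: float
    elution_volume_ul: float
    seawater_volume_ml: float
    dilution_factor: float = 40.0
    detection_limit_copies: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "template_volume_ul", "elution_volume_ul", "seawater_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.copies_per_well < 0:
            raise ValueError("copies_per_well must be non-negative")


def qpcr_copies_per_ml(run: QpcrRun) -> tuple[float, bool]:
    """(copies·mL⁻¹, below_detection) for one run.

    copies·mL⁻¹ = copies_per_well × dilution × (elution/template volumes)
    / seawater mL filtered; the run is below detection when the well count
    is under the assay's detection limit.
    """
    below = run.copies_per_well < run.detection_limit_copies
    copies = (
        run.copies_per_well
        * run.dilution_factor
        * (run.elution_volume_ul / run.template_volume_ul)
        / run.seawater_volume_ml
    )
    return copies, below
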