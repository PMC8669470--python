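"""Biogeography, environment correlations and quantitative conversions.

Flags units endemic to a latitude band (the planted Antarctic-endemic clade
should be the only one), correlates cytometry cell counts with environment
covariates under Bonferroni adjustment, and runs the biomass and qPCR
conversions on the cytometry profiles.

The cryptophyte carbon:volume ratio has no default in the package; the
value used here (220 fg C per um^3, a mid-range literature figure for
cryptophyte-sized flagellates) is this analysis's explicit choice.
"""

from pathlib import Path

import pandas as pd

from cladekey import (
    BiomassParams,
    CytometryRecord,
    QpcrRun,
    biomass,
    endemism_summary,
    pearson_bonferroni,
    qpcr_copies_per_ml,
)
from cladekey.community import CladeAbundanceTable
from cladekey.ecology import load_stations

ROOT = Path(__file__).resolve().parents[1]
SURVEY = ROOT / "results" / "survey"
RESULTS = ROOT / "results"
CRYPTO_RATIO = 220.0  # fg C per um^3, analysis choice (see module docstring)


def main() -> None:
    ab_table = pd.read_csv(RESULTS / "clade_abundance.tsv", sep="\t")
    ab = CladeAbundanceTable(ab_table, tau=10, parent="Cryptophyta")
    stations = load_stations(SURVEY / "stations.tsv")
    es = endemism_summary(ab, stations)
    es.to_csv(RESULTS / "endemism.tsv", sep="\t", index=False)
    endemics = es[es["endemic_band"].notna()]
    print("endemic units:")
    print(endemics[["unit", "endemic_band", "min_lat", "max_lat"]]
          .to_string(index=False))

    cyto = pd.read_csv(SURVEY / "cytometry.tsv", sep="\t")
    cyto_stations = load_stations(SURVEY / "cyto_stations.tsv")
    x = pd.DataFrame(
        {
            "temperature": [s.covariates["temperature"] for s in cyto_stations],
            "chl_a": [s.covariates["chl_a"] for s in cyto_stations],
        }
    )
    y = pd.DataFrame(
        {
            "crypto_cells": cyto["crypto_cells_per_ml"].to_numpy(),
            "noncrypto_cells": (
                cyto["total_cells_per_ml"] - cyto["crypto_cells_per_ml"]
            ).to_numpy(),
        }
    )
    corr = pearson_bonferroni(x, y)
    corr.to_csv(RESULTS / "correlations.tsv", sep="\t", index=False)
    print("\nBonferroni-adjusted Pearson correlations "
          f"(m={corr['m'].iloc[0]} tests):")
    print(corr[["x", "y", "n", "r", "p_adj", "significant"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    params = BiomassParams(crypto_fgC_per_um3=CRYPTO_RATIO)
    rows = []
    for _, r in cyto.iterrows():
        rec = CytometryRecord(
            str(r["station"]), float(r["depth_m"]),
            float(r["total_cells_per_ml"]), float(r["crypto_cells_per_ml"]),
        )
        rows.append({"station": rec.station, **biomass(rec, params)})
    bio = pd.DataFrame(rows)
    bio.to_csv(RESULTS / "biomass.tsv", sep="\t", index=False)
    print(f"\nmean cryptophyte biomass: {bio['crypto_fgC_per_ml'].mean():,.0f} "
          f"fg C/mL over {len(bio)} profiles "
          f"(cell volume {params.crypto_volume_um3:.1f} um^3, "
          f"ratio {CRYPTO_RATIO} fg C/um^3)")

    run = QpcrRun(
        copies_per_well=100, template_volume_ul=2, elution_volume_ul=100,
        seawater_volume_ml=1000, dilution_factor=40,
    )
    copies, below = qpcr_copies_per_ml(run)
    print(f"qPCR worked example: 100 copies/well, 1:40 dilution, 2 uL template, "
          f"100 uL elution, 1 L filtered -> {copies:.0f} copies/mL "
          f"(below detection: {below})")


if __name__ == "__main__":
    main()
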