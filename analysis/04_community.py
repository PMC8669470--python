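"""Clade abundance tables and diversity metrics for the survey.

Aggregates classified reads into per-station unit relative abundances with
the 10-read detection threshold, and computes per-station richness, Shannon
diversity and exact rarefaction curves.
"""

from pathlib import Path

import pandas as pd

from cladekey import clade_abundance, diversity_table, read_asv_table
from cladekey.community import rarefaction_table

ROOT = Path(__file__).resolve().parents[1]
SURVEY = ROOT / "results" / "survey"
RESULTS = ROOT / "results"
TAU = 10


def main() -> None:
    asvs = read_asv_table(SURVEY / "asvs.fasta", SURVEY / "counts.tsv")
    assign = pd.read_csv(RESULTS / "classification.tsv", sep="\t")
    ab = clade_abundance(asvs, assign, parent="Cryptophyta", tau=TAU)
    ab.table.to_csv(RESULTS / "clade_abundance.tsv", sep="\t", index=False)
    det = ab.table.groupby("unit")["detected"].sum()
    print(f"stations with detection (tau={TAU} reads) per unit:")
    print(det.to_string())

    div = diversity_table(asvs.counts)
    div.to_csv(RESULTS / "diversity.tsv", sep="\t", index=False)
    print(f"\nrichness: {div['richness'].mean():.1f} ± {div['richness'].std():.1f}; "
          f"Shannon H: {div['shannon'].mean():.2f} ± {div['shannon'].std():.2f} "
          f"(mean ± sd over {len(div)} stations)")

    depths = [10, 50, 100, 500, 1000, 2000, 5000]
    rt = rarefaction_table(asvs.counts, depths)
    rt.to_csv(RESULTS / "rarefaction.tsv", sep="\t", index=False)
    print(f"rarefaction curves written at depths {depths}")


if __name__ == "__main__":
    main()
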