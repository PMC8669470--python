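"""Classify the survey's ASVs against the diagnostic key.

Exact (100% identity) matching to unit representatives with diagnostic-
position confirmation; outcomes and per-ASV evidence go to
results/classification.tsv.
"""

from pathlib import Path

from cladekey import classify_table, read_asv_table
from cladekey.key import DiagnosticKey

ROOT = Path(__file__).resolve().parents[1]
SURVEY = ROOT / "results" / "survey"
RESULTS = ROOT / "results"


def main() -> None:
    asvs = read_asv_table(SURVEY / "asvs.fasta", SURVEY / "counts.tsv")
    key = DiagnosticKey.from_json(RESULTS / "key.json")
    assign = classify_table(asvs, key, min_identity=100.0)
    assign.to_csv(RESULTS / "classification.tsv", sep="\t", index=False)
    counts = assign["mode"].value_counts().to_dict()
    print(f"classified {len(assign)} ASVs: {counts}")
    total = asvs.counts.to_numpy().sum()
    assigned = sum(
        asvs.counts[row["asv_id"]].sum()
        for _, row in assign.iterrows()
        if row["unit"] not in ("unclassified", "ambiguous")
    )
    print(f"assigned read fraction: {assigned / total:.4f} "
          f"({assigned:,} of {total:,} reads)")


if __name__ == "__main__":
    main()
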