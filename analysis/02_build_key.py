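"""Extract the V9 region by its primers and build the diagnostic key.

Finds the clade-diagnostic columns (synapomorphies) inside the marker
region, merges clades the region cannot tell apart, validates within-clade
identity (variant clades surface here as multi-haplotype), and counts the
endemic clade's unique polymorphisms against its neighbours over the full
gene.
"""

from pathlib import Path

from cladekey import (
    SimConfig,
    build_key,
    count_clade_polymorphisms,
    extract_region,
    load_clade_map,
    read_alignment,
    validate_within_clade,
)

ROOT = Path(__file__).resolve().parents[1]
SURVEY = ROOT / "results" / "survey"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = SimConfig()  # primer defaults
    aln = read_alignment(SURVEY / "reference.afa")
    clades = load_clade_map(SURVEY / "clades.tsv", aln)
    region = extract_region(
        aln, fwd_primer=cfg.fwd_primer, rev_primer=cfg.rev_primer
    )
    print(f"V9 region located at columns {region.start_col}:{region.end_col} "
          f"({region.width} columns) by primer scan")

    key = build_key(region, clades)
    key.to_json(RESULTS / "key.json")
    for u in key.units:
        print(f"  unit {u.label}: {len(u.diagnostics)} diagnostic columns "
              f"{sorted(dict(u.diagnostics))}")

    ident = validate_within_clade(region, clades)
    ident.to_csv(RESULTS / "identity_report.tsv", sep="\t", index=False)
    multi = ident[ident["n_haplotypes"] > 1]
    print(f"multi-haplotype clades in the region: {list(multi['clade'])} "
          f"(max pairwise diff {list(multi['max_pairwise_diff'])})")

    focal = "VII"
    contrast = ["IV", "VI"]
    pc = count_clade_polymorphisms(aln, clades, focal, contrast, scope="full")
    print(f"clade {focal} vs {'+'.join(contrast)}: {pc.count} unique "
          f"polymorphisms across the full gene (columns {pc.columns})")
    with open(RESULTS / "polymorphism_counts.tsv", "w") as fh:
        fh.write("focal\tcontrast\tscope\tcount\tcolumns\n")
        fh.write(f"{focal}\t{','.join(contrast)}\tfull\t{pc.count}\t"
                 f"{','.join(map(str, pc.columns))}\n")


if __name__ == "__main__":
    main()
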