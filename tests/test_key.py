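"""Synapomorphy detection, clade merging and polymorphism counting."""

import numpy as np
import pytest

from cladekey import (
    build_key,
    count_clade_polymorphisms,
    extract_region,
    find_diagnostic_columns,
    merge_indistinguishable,
    simulate_reference_set,
    validate_within_clade,
)
from cladekey.io import CladeMap, ReferenceAlignment
from cladekey.key import DiagnosticKey
from conftest import small_config
from _oracles import diagnostic_columns_oracle


def _aln(rows: dict[str, str]) -> ReferenceAlignment:
    return ReferenceAlignment(list(rows), list(rows.values()))


def _full_region(aln):
    return extract_region(aln, cols=(1, aln.length))


class TestFindDiagnosticColumns:
    def test_single_difference_is_symmetric_diagnostic(self):
        aln = _aln({"a1": "ACGTACGT", "b1": "ACGAACGT"})
        cm = CladeMap({"a1": "A", "b1": "B"})
        key = find_diagnostic_columns(_full_region(aln), cm)
        assert key.diagnostics_of("A") == {4: "T"}
        assert key.diagnostics_of("B") == {4: "A"}

    def test_focal_gap_or_ambiguity_disqualifies_column(self):
        aln = _aln({"a1": "AC-TRCGT", "a2": "AC-TRCGT", "b1": "ACGAACGT"})
        cm = CladeMap({"a1": "A", "a2": "A", "b1": "B"})
        key = find_diagnostic_columns(_full_region(aln), cm)
        # columns 3 (gap) and 5 (R) cannot be diagnostic for A despite fixation
        assert set(key.diagnostics_of("A")) == {4}

    def test_contrast_ambiguity_blocks_compatible_state(self):
        # B carries R = {A,G} at column 4: A's fixed G is carried, no diagnostic
        aln = _aln({"a1": "ACGGACGT", "b1": "ACGRACGT"})
        cm = CladeMap({"a1": "A", "b1": "B"})
        key = find_diagnostic_columns(_full_region(aln), cm)
        assert 4 not in key.diagnostics_of("A")
        # but B's R is ambiguous, so column 4 is no diagnostic for B either
        assert 4 not in key.diagnostics_of("B")

    def test_contrast_gap_does_not_block(self):
        aln = _aln({"a1": "ACGTACGT", "b1": "ACG-ACGT"})
        cm = CladeMap({"a1": "A", "b1": "B"})
        key = find_diagnostic_columns(_full_region(aln), cm)
        assert key.diagnostics_of("A") == {4: "T"}
        # the gap itself carries no state, so it is not diagnostic for B
        assert key.diagnostics_of("B") == {}

    @pytest.mark.parametrize("seed", range(25))
    def test_planted_recovery_and_oracle_equivalence(self, seed):
        cfg = small_config(seed=seed, n_clades=5, diagnostics_per_clade=(0, 4))
        aln, clades, truth = simulate_reference_set(cfg)
        region = extract_region(aln, cols=cfg.region_span)
        key = find_diagnostic_columns(region, clades)
        for unit in key.units:
            assert dict(unit.diagnostics) == truth.diagnostics[unit.label]
            # independent per-column set-logic oracle
            focal = [region.aligned_rows[m] for m in clades.members(unit.label)]
            other = [
                region.aligned_rows[i]
                for i in region.aligned_rows
                if clades.assignments[i] != unit.label
            ]
            oracle_cols = {
                region.column_map[j]
                for j in diagnostic_columns_oracle(focal, other)
            }
            assert set(dict(unit.diagnostics)) == oracle_cols

    def test_monotonicity_adding_contrast_sequence_never_grows_diagnostics(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = 40
            base = "".join(rng.choice(list("ACGT"), size=n))
            rows = {
                "a1": base,
                "a2": base,
                "b1": "".join(rng.choice(list("ACGT"), size=n)),
            }
            cm = CladeMap({"a1": "A", "a2": "A", "b1": "B"})
            before = set(
                find_diagnostic_columns(_full_region(_aln(rows)), cm).diagnostics_of("A")
            )
            rows["b2"] = "".join(rng.choice(list("ACGT"), size=n))
            cm2 = CladeMap({**cm.assignments, "b2": "B"})
            after = set(
                find_diagnostic_columns(_full_region(_aln(rows)), cm2).diagnostics_of("A")
            )
            assert after <= before


class TestMerge:
    def test_identical_haplotype_clades_merge(self):
        aln = _aln({"a1": "ACGTACGT", "b1": "ACGTACGT", "c1": "ACGAACGT"})
        cm = CladeMap({"a1": "III", "b1": "V", "c1": "IV"})
        region = _full_region(aln)
        key = build_key(region, cm)
        assert "III/V" in key.labels and "IV" in key.labels
        assert key.unit("III/V").diagnostics == [(4, "T")]

    def test_pairwise_distinguishable_clades_stay_separate(self):
        aln = _aln({"a1": "AAGT", "b1": "ACGT", "c1": "AGGT"})
        cm = CladeMap({"a1": "A", "b1": "B", "c1": "C"})
        key = build_key(_full_region(aln), cm)
        assert key.labels == ["A", "B", "C"]

    def test_merge_is_order_independent(self):
        rows = {"x1": "ACGTACGT", "y1": "ACGTACGT", "z1": "TCGTACGA"}
        region = _full_region(_aln(rows))
        for order in (["x1", "y1", "z1"], ["z1", "y1", "x1"], ["y1", "z1", "x1"]):
            cm = CladeMap({i: {"x1": "P", "y1": "Q", "z1": "R"}[i] for i in order})
            key = build_key(region, cm)
            assert sorted(key.labels) == ["P/Q", "R"]

    def test_merging_all_clades_warns(self):
        aln = _aln({"a1": "ACGT", "b1": "ACGT"})
        cm = CladeMap({"a1": "A", "b1": "B"})
        region = _full_region(aln)
        pre = find_diagnostic_columns(region, cm)
        with pytest.warns(UserWarning, match="single unit"):
            key = merge_indistinguishable(pre, region, cm)
        assert key.labels == ["A/B"]

    def test_transitive_closure(self):
        # A~B via identity, B~C via identity → one unit of three clades
        rows = {"a1": "ACGT", "b1": "ACGT", "c1": "ACGT", "d1": "AGGT"}
        cm = CladeMap({"a1": "A", "b1": "B", "c1": "C", "d1": "D"})
        key = build_key(_full_region(_aln(rows)), cm)
        assert sorted(key.labels) == ["A/B/C", "D"]


class TestPolymorphismCount:
    def test_identical_sets_count_zero(self):
        aln = _aln({"a1": "ACGTACGT", "b1": "ACGTACGT"})
        cm = CladeMap({"a1": "A", "b1": "B"})
        pc = count_clade_polymorphisms(aln, cm, "A", ["B"], scope="full")
        assert pc.count == 0

    def test_overlapping_focal_contrast_errors(self):
        aln = _aln({"a1": "ACGT"})
        cm = CladeMap({"a1": "A"})
        with pytest.raises(ValueError, match="disjoint"):
            count_clade_polymorphisms(aln, cm, "A", ["A"])

    @pytest.mark.parametrize("seed", range(10))
    def test_full_scope_matches_exhaustive_column_oracle(self, seed):
        cfg = small_config(seed=seed, n_clades=5, extra_gene_diagnostics=(0, 3))
        aln, clades, _ = simulate_reference_set(cfg)
        rng = np.random.default_rng(seed)
        focal = str(rng.choice(clades.clades))
        contrast = [c for c in clades.clades if c != focal][:2]
        pc = count_clade_polymorphisms(aln, clades, focal, contrast, scope="full")
        rows = dict(zip(aln.ids, aln.seqs))
        oracle = diagnostic_columns_oracle(
            [rows[m] for m in clades.members(focal)],
            [rows[m] for c in contrast for m in clades.members(c)],
        )
        assert pc.count == len(oracle)
        assert pc.columns == [j + 1 for j in oracle]

    def test_region_scope_restricts_to_region_columns(self):
        cfg = small_config(seed=3, extra_gene_diagnostics=(2, 2))
        aln, clades, truth = simulate_reference_set(cfg)
        region = extract_region(aln, cols=cfg.region_span)
        focal = clades.clades[0]
        contrast = clades.clades[1:]
        full = count_clade_polymorphisms(aln, clades, focal, contrast, scope="full")
        reg = count_clade_polymorphisms(
            aln, clades, focal, contrast, scope="region", region=region
        )
        rs, re = cfg.region_span
        assert set(reg.columns) == {c for c in full.columns if rs <= c <= re}
        assert full.count == len(truth.gene_diagnostics[focal])


@pytest.fixture(scope="module")
def tpg_like():
    """A synthetic reference set shaped like the nine-clade TPG lineage:
    clades III and V share one V9 haplotype (thus merge), clades IV, VI and
    VII are separated, and clade VII carries eight unique full-gene
    polymorphisms against clades IV ∪ VI."""
    rng = np.random.default_rng(42)
    gene = rng.choice(list("ACGT"), size=400)
    region = slice(300, 380)  # V9-like subregion, columns 301..380

    def variant(cols_states):
        g = gene.copy()
        for col, s in cols_states:
            g[col - 1] = s
        return "".join(g)

    def alt(col):
        return {"A": "C", "C": "G", "G": "T", "T": "A"}[gene[col - 1]]

    # region-diagnostic columns per clade (distinct)
    spec = {
        "III": [(310, alt(310))],
        "V": [(310, alt(310))],  # same haplotype as III inside the region
        "IV": [(320, alt(320)), (321, alt(321))],
        "VI": [(330, alt(330))],
        # clade VII: 3 region + 5 outside-region unique polymorphisms = 8
        "VII": [(340, alt(340)), (341, alt(341)), (342, alt(342)),
                (10, alt(10)), (50, alt(50)), (90, alt(90)),
                (130, alt(130)), (170, alt(170))],
    }
    # distinguish III and V outside the region only
    spec["III"] = spec["III"] + [(200, alt(200))]
    spec["V"] = spec["V"] + [(210, alt(210))]
    rows, labels = {}, {}
    for clade, muts in spec.items():
        for k in range(2):
            sid = f"{clade}_{k + 1}"
            rows[sid] = variant(muts)
            labels[sid] = clade
    return _aln(rows), CladeMap(labels), region

class TestTpgLikeConstruction:
    def test_clades_iii_and_v_merge_but_iv_vii_stay_separate(self, tpg_like):
        aln, cm, region = tpg_like
        rs = extract_region(aln, cols=(region.start + 1, region.stop))
        key = build_key(rs, cm)
        assert "III/V" in key.labels
        assert "IV" in key.labels and "VII" in key.labels and "VI" in key.labels
        assert len(key.diagnostics_of("VII")) == 3

    def test_clade_vii_has_eight_unique_full_gene_polymorphisms(self, tpg_like):
        aln, cm, _ = tpg_like
        pc = count_clade_polymorphisms(aln, cm, "VII", ["IV", "VI"], scope="full")
        assert pc.count == 8


class TestWithinCladeIdentity:
    def test_identical_members_single_haplotype(self):
        aln = _aln({"a1": "ACGT", "a2": "ACGT", "b1": "AGGT"})
        cm = CladeMap({"a1": "A", "a2": "A", "b1": "B"})
        rep = validate_within_clade(_full_region(aln), cm)
        row = rep[rep["clade"] == "A"].iloc[0]
        assert row["n_haplotypes"] == 1 and row["max_pairwise_diff"] == 0

    def test_variant_clade_three_haplotypes_all_pairs_distance(self):
        cfg = small_config(seed=4, variant_clade_prob=1.0, members_per_clade=(3, 4))
        aln, clades, truth = simulate_reference_set(cfg)
        region = extract_region(aln, cols=cfg.region_span)
        rep = validate_within_clade(region, clades).set_index("clade")
        assert truth.variant_clades  # at least one clade got variants
        for clade in clades.clades:
            haps = truth.haplotypes[clade]
            expected_max = max(
                (
                    sum(1 for x, y in zip(h1, h2) if x != y)
                    for i, h1 in enumerate(haps)
                    for h2 in haps[i + 1:]
                ),
                default=0,
            )
            assert rep.loc[clade, "n_haplotypes"] == len(haps)
            assert rep.loc[clade, "max_pairwise_diff"] == expected_max
            if clade in truth.variant_clades:
                assert rep.loc[clade, "n_haplotypes"] == 3


class TestKeySerialization:
    def test_json_round_trip_is_lossless(self, tmp_path, small_reference):
        _, _, clades, region, _ = small_reference
        key = build_key(region, clades)
        path = tmp_path / "key.json"
        key.to_json(path)
        back = DiagnosticKey.from_json(path)
        assert back.labels == key.labels
        for u, v in zip(key.units, back.units):
            assert u == v
        assert (back.region_start, back.region_end) == (key.region_start, key.region_end)
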