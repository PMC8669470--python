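"""Abundance thresholding, Shannon/richness, exact rarefaction."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cladekey import clade_abundance, diversity_table, rarefaction, shannon_richness
from cladekey.io import AsvTable
from _oracles import rarefaction_oracle, shannon_oracle


def _table(counts: dict[str, dict[str, int]], unit_of: dict[str, str]):
    """Build an AsvTable + assignment frame from {sample: {asv: n}}."""
    asv_ids = sorted({a for row in counts.values() for a in row})
    seqs = {a: "ACGT" * 10 for a in asv_ids}
    mat = pd.DataFrame(
        [[counts[s].get(a, 0) for a in asv_ids] for s in counts],
        index=list(counts), columns=asv_ids, dtype=np.int64,
    )
    table = AsvTable(seqs, mat, {a: "Cryptophyta" for a in asv_ids})
    assign = pd.DataFrame(
        {"asv_id": asv_ids, "unit": [unit_of[a] for a in asv_ids]}
    )
    return table, assign


class TestCladeAbundance:
    def test_detection_threshold_boundary_is_exact(self):
        table, assign = _table(
            {"s1": {"a": 9, "b": 10, "c": 100}},
            {"a": "VII", "b": "IV", "c": "I"},
        )
        ab = clade_abundance(table, assign, tau=10).table.set_index("unit")
        assert not ab.loc["VII", "detected"]  # 9 reads: below the threshold
        assert ab.loc["IV", "detected"]  # 10 reads: exactly at it
        # the computed abundance is retained even when not detected
        assert ab.loc["VII", "rel_abund"] == pytest.approx(9 / 119)

    def test_single_unit_holding_all_reads_is_one(self):
        table, assign = _table({"s1": {"a": 1000}}, {"a": "VII"})
        ab = clade_abundance(table, assign).table
        assert ab["rel_abund"].iloc[0] == 1.0

    def test_unclassified_reads_stay_in_denominator(self):
        table, assign = _table(
            {"s1": {"a": 50, "u": 50}}, {"a": "VII", "u": "unclassified"}
        )
        ab = clade_abundance(table, assign).table
        assert ab["rel_abund"].iloc[0] == pytest.approx(0.5)
        assert ab["parent_total"].iloc[0] == 100

    def test_zero_parent_sample_flagged_not_error(self):
        table, assign = _table(
            {"s1": {"a": 10}, "s2": {"a": 0}}, {"a": "VII"}
        )
        ab = clade_abundance(table, assign).table.set_index("sample")
        assert np.isnan(ab.loc["s2", "rel_abund"])

    def test_missing_parent_label_errors(self):
        table, assign = _table({"s1": {"a": 1}}, {"a": "VII"})
        with pytest.raises(ValueError, match="absent"):
            clade_abundance(table, assign, parent="Diatomea")

    @pytest.mark.parametrize("seed", range(10))
    def test_unit_reads_match_brute_force_summation(self, seed):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(4)]
        asvs = [f"a{i}" for i in range(20)]
        units = ["I", "II", "III", "unclassified", "ambiguous"]
        unit_of = {a: str(rng.choice(units)) for a in asvs}
        counts = {
            s: {a: int(rng.integers(0, 50)) for a in asvs} for s in samples
        }
        table, assign = _table(counts, unit_of)
        ab = clade_abundance(table, assign, tau=10)
        for s in samples:
            sub = ab.table[ab.table["sample"] == s]
            for _, row in sub.iterrows():
                expected = sum(
                    counts[s][a] for a in asvs if unit_of[a] == row["unit"]
                )
                assert row["reads"] == expected
            # conservation: unit reads + unclassified/ambiguous = parent total
            leftover = sum(
                counts[s][a] for a in asvs
                if unit_of[a] in ("unclassified", "ambiguous")
            )
            assert sub["reads"].sum() + leftover == sum(counts[s].values())


class TestShannonRichness:
    def test_uniform_four_taxa_closed_form(self):
        s, h = shannon_richness([25, 25, 25, 25])
        assert s == 4 and h == pytest.approx(math.log(4))

    def test_single_taxon_is_zero_entropy(self):
        assert shannon_richness([0, 42, 0]) == (1, 0.0)

    def test_all_zero_sample_flagged(self):
        s, h = shannon_richness([0, 0])
        assert s == 0 and math.isnan(h)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_vectors_match_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 1000, size=30)
        s, h = shannon_richness(counts)
        assert s == int((counts > 0).sum())
        assert h == pytest.approx(shannon_oracle(list(counts)), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=30))
    def test_entropy_bounded_by_log_richness(self, counts):
        s, h = shannon_richness(counts)
        if s == 0:
            assert math.isnan(h)
        else:
            assert -1e-12 <= h <= math.log(s) + 1e-12


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        counts = [5, 3, 2, 0, 1]
        assert rarefaction(counts, [11])[0] == pytest.approx(4.0, abs=1e-12)

    def test_depth_one_is_one(self):
        assert rarefaction([5, 3, 2], [1])[0] == pytest.approx(1.0)

    def test_depth_beyond_total_errors(self):
        with pytest.raises(ValueError, match="depths"):
            rarefaction([2, 2], [5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_combinatorial_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 60, size=12)
        total = int(counts.sum())
        for depth in (1, total // 3, total):
            got = rarefaction(counts, [depth])[0]
            assert got == pytest.approx(rarefaction_oracle(counts, depth), rel=1e-10)

    def test_monte_carlo_subsampling_agreement(self):
        rng = np.random.default_rng(11)
        counts = np.array([40, 25, 10, 5, 3, 1, 1])
        depth = 30
        expected = rarefaction(counts, [depth])[0]
        draws = 2000
        richness = np.empty(draws)
        for k in range(draws):
            sub = rng.multivariate_hypergeometric(counts, depth)
            richness[k] = (sub > 0).sum()
        se = richness.std(ddof=1) / math.sqrt(draws)
        assert abs(richness.mean() - expected) <= 3 * se

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=80), min_size=2, max_size=15)
           .filter(lambda c: sum(c) >= 4))
    def test_curve_nondecreasing_and_concave(self, counts):
        total = sum(counts)
        depths = list(range(0, total + 1))
        curve = rarefaction(counts, depths)
        diffs = np.diff(curve)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()


class TestVeganCrossCheck:
    """Independent oracle: the reference R implementation of the same
    diversity formulas, run on a tiny fixed count table."""

    def test_shannon_and_rarefy_agree_with_vegan(self, tmp_path):
        counts = [17, 9, 4, 1, 1, 0]
        depth = 12
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(vegan))\n"
            f"x <- c({','.join(map(str, counts))})\n"
            f"cat(diversity(x, index='shannon'), rarefy(x, {depth}), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        ).stdout.split()
        r_shannon, r_rarefy = float(out[0]), float(out[1])
        _, h = shannon_richness(counts)
        assert h == pytest.approx(r_shannon, abs=1e-6)
        assert rarefaction(counts, [depth])[0] == pytest.approx(r_rarefy, abs=1e-6)


class TestDiversityTable:
    def test_per_sample_metrics(self):
        mat = pd.DataFrame(
            [[10, 10, 10, 10], [5, 0, 0, 0]], index=["a", "b"],
            columns=list("wxyz"),
        )
        div = diversity_table(mat).set_index("sample")
        assert div.loc["a", "richness"] == 4
        assert div.loc["a", "shannon"] == pytest.approx(math.log(4))
        assert div.loc["b", "shannon"] == 0.0
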