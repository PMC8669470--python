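"""Recovery and calibration experiments over the synthetic generator.

Each function runs the pipeline end to end on simulator output and
measures how well it recovers the planted truth, or how well a statistical
procedure keeps its nominal guarantees.  These are the package's principal
validation quantities; both the test suite and ``scripts/acceptance.py``
call them.

Problem sizes are chosen so the full battery runs in a few minutes on one
CPU: short genes (300–400 columns) with a ~120-column marker region, a
handful of stations at a few thousand reads, and the replicate counts
stated in each docstring.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .classify import classify_table
from .community import clade_abundance, rarefaction, shannon_richness
from .ecology import endemism_summary, pearson_bonferroni
from .io import extract_region
from .key import build_key, count_clade_polymorphisms, find_diagnostic_columns
from .simulate import (
    SimConfig,
    per_read_error_probability,
    simulate_cyto_env,
    simulate_reference_set,
    simulate_survey,
)

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"}, "-": set(), ".": set(),
}


def _derive(seed: int, i: int) -> int:
    return (seed * 100_003 + i * 7_919 + 1) % (2**31)


def _small(seed: int, **overrides) -> SimConfig:
    defaults = dict(
        seed=seed,
        gene_length=400,
        region_span=(250, 369),
        members_per_clade=(1, 3),
        diagnostics_per_clade=(1, 3),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def _column_predicate_oracle(focal_rows, other_rows):
    """Independent set-logic evaluation of the diagnostic predicate,
    column by column (no bit tricks, no vectorisation)."""
    hits = []
    for j in range(len(focal_rows[0])):
        states = {r[j] for r in focal_rows}
        if len(states) != 1:
            continue
        s = next(iter(states))
        if s not in "ACGT":
            continue
        if any(s in _IUPAC_SETS[r[j]] for r in other_rows):
            continue
        hits.append(j)
    return hits


# ---------------------------------------------------------------------------


def synapomorphy_recovery(seed: int, n_sims: int = 200) -> dict:
    """Planted-synapomorphy recovery over random reference sets.

    Each replicate draws 3–10 clades of 1–6 members with 0–10 planted
    diagnostic columns per clade (variant clades allowed) and asks whether
    the detected per-clade diagnostic sets equal the planted sets exactly.
    Returns the fraction of replicates with perfect recovery.
    """
    meta_rng = np.random.default_rng(seed)
    exact = 0
    for i in range(n_sims):
        k = int(meta_rng.integers(3, 11))
        cfg = SimConfig(
            seed=_derive(seed, i),
            n_clades=k,
            members_per_clade=(1, 6),
            diagnostics_per_clade=(0, 10),
        )
        aln, clades, truth = simulate_reference_set(cfg)
        region = extract_region(aln, cols=cfg.region_span)
        key = find_diagnostic_columns(region, clades)
        if all(
            dict(u.diagnostics) == truth.diagnostics[u.label] for u in key.units
        ):
            exact += 1
    return {"value": exact / n_sims, "n": n_sims}


def oracle_agreement(seed: int, n_sims: int = 30) -> dict:
    """Agreement of diagnostic detection and polymorphism counting with an
    independent brute-force per-column predicate, per simulated instance."""
    meta_rng = np.random.default_rng(seed + 1)
    agree = 0
    for i in range(n_sims):
        cfg = _small(
            _derive(seed, 10_000 + i),
            n_clades=int(meta_rng.integers(3, 8)),
            diagnostics_per_clade=(0, 4),
            extra_gene_diagnostics=(0, 3),
        )
        aln, clades, _ = simulate_reference_set(cfg)
        region = extract_region(aln, cols=cfg.region_span)
        key = find_diagnostic_columns(region, clades)
        ok = True
        for u in key.units:
            focal = [region.aligned_rows[m] for m in clades.members(u.label)]
            other = [
                region.aligned_rows[x]
                for x in region.aligned_rows
                if clades.assignments[x] != u.label
            ]
            oracle = {
                region.column_map[j]
                for j in _column_predicate_oracle(focal, other)
            }
            ok &= set(dict(u.diagnostics)) == oracle
        focal_clade = str(meta_rng.choice(clades.clades))
        contrast = [c for c in clades.clades if c != focal_clade][:2]
        pc = count_clade_polymorphisms(aln, clades, focal_clade, contrast, "full")
        rows = dict(zip(aln.ids, aln.seqs))
        pc_oracle = _column_predicate_oracle(
            [rows[m] for m in clades.members(focal_clade)],
            [rows[m] for c in contrast for m in clades.members(c)],
        )
        ok &= pc.count == len(pc_oracle)
        agree += ok
    return {"value": agree / n_sims, "n": n_sims}


def classification_recovery(seed: int) -> dict:
    """Noiseless and error-perturbed classification of a simulated survey.

    Noiseless reads must classify 100% to their source units; at a 0.1%
    per-base substitution rate with the exact-identity rule, the
    unclassified read fraction is compared with the analytic per-read error
    probability 1 − (1 − e)^L.
    """
    base = dict(
        n_clades=6, n_stations=5, depth_range=(2000, 2000),
        variant_clade_prob=0.0, diagnostics_per_clade=(2, 4),
    )
    out: dict = {}
    # noiseless
    cfg = _small(_derive(seed, 20_000), error_rate=0.0, **base)
    aln, clades, truth = simulate_reference_set(cfg)
    key = build_key(extract_region(aln, cols=cfg.region_span), clades)
    asvs, _ = simulate_survey(cfg, truth)
    assign = classify_table(asvs, key)
    unit_of_hap = {h: c for c in truth.haplotypes for h in truth.haplotypes[c]}
    totals = asvs.counts.sum(axis=0)
    good = sum(
        totals[row["asv_id"]]
        for _, row in assign.iterrows()
        if row["unit"] == unit_of_hap[asvs.sequences[row["asv_id"]]]
    )
    n_reads = int(totals.sum())
    out["noiseless_accuracy"] = {"value": good / n_reads, "n": n_reads}
    # 0.1% per-base error, min_identity = 100
    cfg = _small(_derive(seed, 20_001), error_rate=0.001, **base)
    aln, clades, truth = simulate_reference_set(cfg)
    key = build_key(extract_region(aln, cols=cfg.region_span), clades)
    asvs, _ = simulate_survey(cfg, truth)
    assign = classify_table(asvs, key, min_identity=100.0)
    totals = asvs.counts.sum(axis=0)
    uncl = sum(
        totals[row["asv_id"]]
        for _, row in assign.iterrows()
        if row["unit"] in ("unclassified", "ambiguous")
    )
    n_reads = int(totals.sum())
    region_len = cfg.region_span[1] - cfg.region_span[0] + 1
    p = per_read_error_probability(cfg.error_rate, region_len)
    frac = uncl / n_reads
    se = math.sqrt(p * (1 - p) / n_reads)
    out["error_unclassified_fraction"] = {"value": frac, "n": n_reads}
    out["error_unclassified_expected"] = {"value": p, "n": n_reads}
    out["error_unclassified_zscore"] = {"value": (frac - p) / se, "n": n_reads}
    return out


def detection_rule_check() -> dict:
    """Exact threshold semantics: 9 reads not detected, 10 reads detected."""
    from .io import AsvTable

    seqs = {"a": "ACGT" * 20, "b": "AGGT" * 20, "c": "ATGT" * 20}
    counts = pd.DataFrame(
        [[9, 10, 981]], index=["s1"], columns=["a", "b", "c"], dtype=np.int64
    )
    table = AsvTable(seqs, counts, {k: "Cryptophyta" for k in seqs})
    assign = pd.DataFrame(
        {"asv_id": ["a", "b", "c"], "unit": ["VII", "IV", "I"]}
    )
    ab = clade_abundance(table, assign, tau=10).table.set_index("unit")
    return {
        "reads_9_detected": {"value": int(ab.loc["VII", "detected"]), "n": 1},
        "reads_10_detected": {"value": int(ab.loc["IV", "detected"]), "n": 1},
    }


def diversity_checks(seed: int, mc_draws: int = 10_000) -> dict:
    """Closed-form and Monte-Carlo validation of the diversity formulas.

    The uniform four-taxon Shannon value, rarefaction at full depth versus
    observed richness, and the exact rarefaction expectation against the
    mean of ``mc_draws`` without-replacement subsamples (z-score reported).
    """
    _, h4 = shannon_richness([25, 25, 25, 25])
    counts = np.array([120, 60, 30, 15, 8, 4, 2, 1, 1, 1])
    s_obs = int((counts > 0).sum())
    full = float(rarefaction(counts, [int(counts.sum())])[0])
    depth = 40
    expected = float(rarefaction(counts, [depth])[0])
    rng = np.random.default_rng(seed + 2)
    richness = np.empty(mc_draws)
    for k in range(mc_draws):
        sub = rng.multivariate_hypergeometric(counts, depth)
        richness[k] = int((sub > 0).sum())
    se = richness.std(ddof=1) / math.sqrt(mc_draws)
    return {
        "shannon_uniform4": {"value": h4, "n": 4},
        "rarefaction_full_depth_minus_richness": {
            "value": abs(full - s_obs), "n": s_obs,
        },
        "rarefaction_mc_zscore": {
            "value": (float(richness.mean()) - expected) / se, "n": mc_draws,
        },
    }


def fwer_null(seed: int, reps: int = 10_000, n: int = 30) -> dict:
    """Familywise error of the Bonferroni-adjusted Pearson procedure under
    a simulated global null (5 covariates × 2 taxa = 10 tests per family)."""
    rng = np.random.default_rng(seed + 3)
    hits = 0
    xcols = list("abcde")
    for _ in range(reps):
        x = pd.DataFrame(rng.standard_normal((n, 5)), columns=xcols)
        y = pd.DataFrame(rng.standard_normal((n, 2)), columns=["u", "v"])
        res = pearson_bonferroni(x, y)
        hits += int(res["significant"].any())
    return {"value": hits / reps, "n": reps}


def temperature_effect_power(seed: int, reps: int = 1000) -> dict:
    """Power to recover the planted positive temperature effect on
    cryptophyte cell counts (Bonferroni-adjusted over the covariates
    tested), at the generator's default effect size."""
    detected = 0
    for i in range(reps):
        cfg = SimConfig(seed=_derive(seed, 30_000 + i))
        cyto, stations = simulate_cyto_env(cfg)
        x = pd.DataFrame(
            {
                "temperature": [s.covariates["temperature"] for s in stations],
                "chl_a": [s.covariates["chl_a"] for s in stations],
            }
        )
        y = pd.DataFrame({"crypto": [c.crypto_cells_per_ml for c in cyto]})
        res = pearson_bonferroni(x, y)
        row = res[(res["x"] == "temperature")].iloc[0]
        detected += int(row["significant"] and row["r"] > 0)
    return {"value": detected / reps, "n": reps}


def endemism_recovery(seed: int, n_seeds: int = 100) -> dict:
    """Recovery of the planted south-endemic unit across surveys.

    With error-free reads and per-band expected reads far above the
    detection threshold, exactly the planted unit must be flagged endemic
    (to the Antarctic band) and every other unit endemic nowhere.
    """
    correct = 0
    for i in range(n_seeds):
        cfg = _small(
            _derive(seed, 40_000 + i),
            n_clades=6, endemic_clade_index=3, n_stations=10,
            depth_range=(3000, 3000), error_rate=0.0,
        )
        aln, clades, truth = simulate_reference_set(cfg)
        key = build_key(extract_region(aln, cols=cfg.region_span), clades)
        asvs, stations = simulate_survey(cfg, truth)
        assign = classify_table(asvs, key)
        ab = clade_abundance(asvs, assign, tau=cfg.tau)
        es = endemism_summary(ab, stations).set_index("unit")
        flags = {
            u: es.loc[u, "endemic_band"] for u in es.index
        }
        want = {
            u: ("antarctic" if u == truth.endemic_clade else None)
            for u in es.index
        }
        correct += int(flags == want)
    return {"value": correct / n_seeds, "n": n_seeds}
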