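# Methods

This note records the models, rules and numerical choices behind each
stage of the pipeline, the conditions the synthetic-data generator
emulates, and the limitations a user should keep in mind.

## Coordinates and alphabet

Alignment columns and degapped positions are 1-based and inclusive
(GenBank feature convention). Sequences are normalised to uppercase with
U→T on ingest. Bases are held as 4-bit masks (A=1, C=2, G=4, T=8); an
IUPAC ambiguity code is the OR of its expansion and a gap is 0, so "state
*s* is carried by code *x*" is a bitwise test. Gaps therefore carry no
state: they are compatible with nothing, including other gaps.

## Region extraction

The marker subregion is cut from the reference alignment either by an
explicit column span or by locating the amplification primer pair. Primer
search scans each row with gaps elided (primers are defined on ungapped
sequence), maps the hit back to alignment columns, and takes the columns
strictly between the forward-primer end and the reverse-complemented
reverse-primer start. Degenerate primer positions match any compatible
base. The default mismatch budget is 2 substitutions per primer, enough to
tolerate reference polymorphism at annealing sites without false
anchoring; rows where both primers are found must agree on one span, and
disagreement is a hard error (it indicates an inconsistent alignment), as
is failure to anchor at all (the error suggests an explicit span).

## Diagnostic predicate

A region column *j* is diagnostic (a synapomorphy) for clade *C* when

* every member of *C* carries the same **unambiguous** base *s* at *j* —
  a gap or ambiguity code anywhere in the focal clade disqualifies the
  column (fixation is required, so clades with internal variants simply
  yield no diagnostic at their variable columns), and
* no sequence outside *C* carries a base compatible with *s* — ambiguity
  codes in outside sequences count as carrying every base in their
  expansion (conservative: an N blocks the column), while an outside gap
  neither blocks nor satisfies the test.

Indels are never diagnostic; the predicate counts nucleotide states only.
Two structural properties follow and are verified by tests: adding a
sequence to a non-focal clade can only shrink a focal clade's diagnostic
set, and with exactly **two** clades every planted substitution separates
both clades symmetrically (the non-mutated clade is fixed for an ancestral
state the mutated clade no longer carries), so exact per-clade recovery of
planted columns is a ≥3-clade property.

Polymorphism counting (`count_clade_polymorphisms`) evaluates the same
predicate with the outside set restricted to a chosen contrast set, over
either the region or the full alignment. Because the focal/contrast
membership and the gap rule fully determine the count, the choice of
representatives inside the focal clade matters only through fixation.

## Merging indistinguishable clades

Clades *A* and *B* merge into one classification unit when no region
column is diagnostic for *A* against *{B}* nor for *B* against *{A}* —
i.e. their region haplotype sets are state-indistinguishable. Merging is
the transitive closure of this pairwise relation (union–find), so the
result is independent of clade input order; merged units are labelled by
their lexicographically sorted member clades ("III/V"). Unit diagnostics
are recomputed against all non-member clades after merging. Collapse of
all clades into one unit is legal and emits a warning. The key serialises
to JSON with its region provenance and per-representative position maps so
classification is reproducible bit for bit.

## Percent identity and classification

Identity is defined by an optimal **semi-global** alignment — terminal
gaps free on both sequences — under match +1, mismatch −1, gap −2
(config-exposed). Percent identity is matches over alignment columns with
terminal-overhang columns excluded; IUPAC-compatible pairs count as
matches. Traceback ties break deterministically (diagonal > up > left;
start cell prefers the bottom-right corner, then the bottom row, then the
right column). Scores are small integer sums held in float64, so the
traceback's equality tests are exact. This is deliberately not a local
heuristic: BLAST-style identities from the literature are approximated,
and any definitional drift can be diagnosed from the recorded alignment.

An ASV is scored against every unit representative. It is assigned to the
best unit when (a) best identity ≥ `min_identity` (default 100, the
exact-match rule; configurable for sensitivity analysis) and (b) every
diagnostic column of that unit lying inside the aligned overlap is matched
by a compatible ASV base — the explicit, automated stand-in for a manual
confirmation step, and flagged as such. Ties at the decision boundary are
returned as "ambiguous"; queries shorter than half the mean representative
length are returned "unclassified" with a length note rather than raising.
A query equal in length to a representative and IUPAC-compatible at every
position takes a fast path to 100% (that gapless alignment attains the
maximal score).

## Abundance, detection and diversity

Unit reads are summed over assigned ASVs per sample; relative abundance
divides by the **parent-taxon** total of that sample, keeping unclassified
and ambiguous reads in the denominator. A sample's unit is "detected" when
its reads ≥ τ (default 10) — exact integer semantics, 9 is below and 10 at
the threshold — and the computed abundance is retained alongside the flag
rather than zeroed, so maps and downstream tables remain reproducible.
Samples with zero parent reads carry NaN abundances, never a division
error.

Richness is the count of taxa with positive reads; Shannon uses the
natural log (a log2 switch exists but is off by default); both are
computed on raw, unrarefied counts by default. Rarefaction is the exact
hypergeometric expectation evaluated with log-gamma (numerically stable
for any depth), not a resampling estimate — deterministic, and the same
definition as the standard R implementation, which one test uses as an
independent cross-check.

## Ecology

* **Endemism**: samples map to stations; stations fall into latitude bands
  (default edges −90, −60, −23.5, 23.5, 60, 90: Antarctic,
  south-temperate, tropical, north-temperate, Arctic; configurable). A
  unit is endemic to a band when its detected samples lie in that band and
  no other. Per-band detection frequency (fraction of the band's stations)
  and mean within-parent share are reported alongside the min/max
  detection latitudes.
* **Correlations**: Pearson *r* by the product-moment formula, *p* from
  the t-transform with n−2 df, Bonferroni adjustment with family size m =
  all pairs computed in the call (reported in the output, since family
  choice is otherwise invisible). Missing values are deleted pairwise;
  pairs with fewer than 3 complete observations or zero variance are
  flagged NaN, not dropped from m.
* **Biomass**: cryptophyte cell volume uses a prolate spheroid,
  (π/6)·L·W², on measured length × width (defaults 11.3 × 5.1 μm); other
  phytoplankton a sphere, (π/6)·d³, at d = 5.5 μm with 237 fg C·μm⁻³. The
  model is an explicit, swappable choice. The cryptophyte carbon:volume
  ratio has **no default**: the literature sources give values for the
  user's taxon and the package refuses to guess (the demo analysis states
  its own choice of 220 fg C·μm⁻³).
* **qPCR**: copies·mL⁻¹ = copies/well × dilution × (elution/template
  volume) / seawater mL filtered; wells under the assay detection limit
  (default 10 copies/well, dilution default 1:40) are flagged below
  detection. All conversions are exactly linear in their inputs, which the
  tests exercise as scaling laws.

## Synthetic-data generator

The generator emulates the statistical structure of a clade-resolved
amplicon survey; defaults are the study conditions of the motivating
system:

* **Reference**: 9 clades over a 1,649-column gene with a 130-column V9
  region (columns 1480–1609) flanked by planted primers; 2–6 members per
  clade; 2–4 planted clade-specific substitutions per clade at distinct
  columns (the true synapomorphies); each clade internally identical
  except variant clades (probability 2/9, echoing two of nine clades)
  which carry three haplotypes differing by 1 nt from the base haplotype.
* **Survey**: 25 stations cycling through the five latitude bands;
  2,000–20,000 parent-taxon reads per station drawn multinomially from a
  niche model — Gaussian latitudinal niches (width 30°) over a uniform
  baseline (0.25), with one planted endemic clade (the seventh, "VII")
  present only south of −60° at weight 3 (dominant there, mirroring the
  motivating system's Antarctic dominance). Per-base substitution errors
  are applied per read at a configurable rate; the default is 0 because
  field inputs are denoised ASVs, and 0.1% models residual error. Indels
  are not simulated by default, matching the substitution-only diagnostic
  semantics.
* **Cytometry/environment**: 42 profiles with temperature uniform on
  −1.8…2.0 °C and cryptophyte cells·mL⁻¹ = exp(7.5 + 0.8·T + ε),
  ε ~ N(0, 0.35²) — a planted log-linear positive temperature effect whose
  intercept/slope put peak abundances near 10⁴ cells·mL⁻¹; other
  photosynthetic cells are drawn independently of temperature so the
  effect is group-specific.
* **Determinism**: each artifact (reference / survey / cytometry) draws
  from its own stream derived from the master seed by a fixed offset, so
  regenerating one stage never perturbs another; all outputs are
  byte-identical across runs for a given seed (floats written at fixed
  precision).

What the generator does **not** emulate: phylogenetic sequence evolution
(no substitution model — diagnostics are planted, not evolved), PCR
chimeras, indel errors (off by default), copy-number variation between
taxa, or spatial autocorrelation beyond the latitude niche. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
logic under its stated assumptions, not robustness to reference
misannotation or alignment error in real data.

## Validation battery and problem sizes

`cladekey.evaluation` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: exact planted-synapomorphy recovery over
200 random 3–10-clade reference sets; agreement of detection and
polymorphism counting with an independent per-column set-logic oracle on
30 instances; classification recovery on 10,000-read surveys (noiseless
accuracy, and at 0.1% per-base error the unclassified fraction against the
analytic 1 − (1−e)^L within binomial error); exact detection-threshold
semantics; diversity closed forms plus a 10,000-draw Monte-Carlo
rarefaction check; familywise-error calibration of the Bonferroni-Pearson
procedure under a 10,000-replicate null and its power (1,000 replicates)
for the planted temperature effect; and endemism recovery over 100
surveys. Experiments use short genes (300–400 columns, ~120-column
region) and a handful of stations so the whole battery completes in about
a minute on one CPU; the replicate counts, not the per-instance sizes,
carry the statistical weight.

## Known limitations

* Classification is representative-based: a unit without a representative
  spanning the query cannot be assigned, and identity to a representative
  is not identity to the clade's ancestor.
* The semi-global identity can reach 100% on a short perfect overlap; the
  half-length guard rejects grossly short queries, but screening
  fragmentary external data sets deserves a stricter overlap rule.
* Diagnostic detection treats the clade labels as ground truth; label
  errors propagate silently into the key (mitigated by the within-clade
  identity report, which flags unexpected variation).
* Bonferroni control is conservative for correlated covariate families;
  the family size is reported so users can substitute other corrections.
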