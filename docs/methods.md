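# Methods

This note documents the models and procedures implemented in `asodesign`,
their assumptions, the parameters that matter, and the design choices made
where more than one reasonable construction existed.

## 1. Transcript pair and coordinates

A locus is an ordered list of exons. Skipping one internal exon yields the
mutant transcript; skipping a terminal exon is rejected because it creates
no novel exon–exon junction, and the junction is the whole point. All
coordinates are 0-based and half-open; a junction is an inter-residue
offset (junction *j* sits between positions *j−1* and *j*). The mutant →
wild-type coordinate map is the identity left of the junction and a shift
by the skipped length right of it; it is total and strictly increasing, and
re-inserting the skipped exon at the junction reconstructs the wild-type
sequence exactly (a tested invariant). The in-frame flag is simply
`skipped_length % 3 == 0`.

Structure prediction operates on junction-centered windows (default
lengths 200–2500 nt; any length ≥ 2 is accepted). The junction is placed at
offset ⌊L/2⌋ — the tie-break for odd lengths is ours. Windows that would
overrun a transcript end are truncated on that side only (flag +
warning) rather than rejected: centered windows presume long transcripts,
and a hard error would make short synthetic loci unusable.

The internal alphabet is RNA; `T` is normalized to `U` on input, and FASTA
output can restore the DNA alphabet with a flag.

## 2. Secondary-structure ensembles and ss-count

### Energy model

The folding engine scores a nested structure as

    E(s) = Σ_pairs e(a·b) + σ · #stacks

with per-pair scores `e(G·C) = −3`, `e(A·U) = −2`, `e(G·U) = −1` (model
units, configurable), a stacking bonus `σ = −2` for every pair (i, j) whose
inner neighbor (i+1, j−1) is also paired, minimum hairpin loop of 3
unpaired nucleotides, and no pseudoknots. The stacking term is essential,
not cosmetic: with independent per-pair scores, the Boltzmann ensemble is
dominated by combinatorially many arrangements of scattered isolated pairs,
and no specific helix — including a deliberately planted one — ever closes
a region decisively. Cooperativity through σ is the minimal correction that
makes contiguous helices beat scattered pairs, which is also the physically
correct picture (RNA duplex stability is stacking-dominated). Full
nearest-neighbor loop thermodynamics remains out of scope; the package's
contribution is the accessibility logic, and externally computed ensembles
can be imported (CT or dot-bracket) whenever higher-fidelity structures are
wanted.

### Two regimes

* **Exhaustive** (length ≤ 25, configurable): every valid structure within
  an energy band ε = 2 of the optimum, enumerated by the unique
  decomposition "position i is unpaired, or i pairs k", with lower-bound
  pruning from interval tables E(i,j) and E_b(i,j) (minimum energy given
  that i pairs j). The result is deterministically ordered by (energy,
  pairing). The test suite checks this against an independent brute-force
  enumerator over all nested pairings.
* **Sampled** (longer sequences): exact partition-function tables
  Z(i,j)/Z_b(i,j) under the same decomposition (log-space, with the
  stacked continuation carrying weight `s = exp(−σ/kT)`), then seeded
  stochastic traceback of `n_samples = 30` structures at `kT = 1`. The
  sample size matches the ensemble scale at which ss-counts are usually
  reported; the minimum-energy structure is always included (it replaces
  the last sample if not drawn). The sampler was validated against exact
  Boltzmann probabilities on exhaustively enumerable sequences.

The O(n³) tables keep window folding practical to a few hundred
nucleotides; the packaged pipeline uses 160-nt windows (seconds per
window), a deliberate problem-size choice for the synthetic locus rather
than a statement about the method's limits.

### ss-count and classes

`ss_count[i]` is the number of ensemble structures in which position *i* is
unpaired; `ss_fraction = ss_count / n_structures` is the cross-window
currency (raw counts are not comparable between ensembles of different
size). Classification uses symmetric tertiles by default: open at
fraction ≥ 2/3, closed at ≤ 1/3, semi-open between — reproducing the
three-color (green/yellow/red) heatmap semantics; both thresholds are
configurable, and inclusive boundaries are part of the contract.
A tabular heatmap export reconciles several window lengths per position by
majority vote, ties resolving to semi-open.

### Differential map

Mutant and wild-type windows are aligned through the exon coordinate map
(how the published analysis reconciled its two differently-centered windows
is unstated; the coordinate map is our construction). Two position sets are
extracted, both in mutant coordinates:

* `mut_accessible_wt_closed` — mutant open *or semi-open*, wild-type
  closed: where added binding affinity is mutant-specific;
* `open_in_both` — strictly open on both alleles (optionally restricted to
  a named exon): candidate sites for discriminating mismatches.

Positions whose wild-type image falls outside the profiled wild-type
window are skipped; zero overlap is an error. The map also records the
per-position accessibility margin (mutant minus wild-type fraction), used
as a tie-break downstream.

## 3. Oligonucleotide model

A design is a 5′→3′ residue list (base, sugar, backbone). Notation:
square/angle/curly brackets mark 2′-OMe / 2′-MOE / LNA runs; a `∗` (or
`*`) suffix marks a PS-DNA residue. DNA is written with T, 2′-OMe with U;
2′-MOE and LNA accept both (printed tables use the 5-methyl-U convention
for those chemistries). All residues default to a phosphorothioate
backbone — wing backbone chemistry is rarely stated in design tables and PS
throughout is the therapeutic standard — so the star is treated as a sugar
marker, with a config override for PO. Serialization is canonical (single
spaces between runs) and `parse ∘ serialize` is the identity on residues.

Category inference is structural: one maximal DNA run → gapmer, two or
more → mixmer, declared mismatch positions → mismatch-mixmer. The packaged
table carries the printed family label separately (`printed_category`)
because one printed "gapmer" row has an interleaved pattern that the run
rule correctly calls a mixmer.

**Metrics.** GC% is reported to one decimal. Tm uses Biopython's
nearest-neighbor RNA/DNA-hybrid table (Sugimoto) at 50 mM Na⁺ / 250 nM
oligo by default, plus additive per-residue increments for
affinity-raising sugars (LNA +3.0 °C, 2′-MOE +1.0 °C, 2′-OMe +0.7 °C —
mid-range literature values per modified residue); designs shorter than
8 nt fall back to the Wallace rule. This Tm is a model-based analogue for
ranking — printed Tm columns from vendor tools with undisclosed settings
are never matched numerically, only ordinal and monotonicity properties
are asserted. DNA-run profiles flag RNase H competence at a configurable
minimum run (default 4 consecutive PS-DNA residues; 3 admits
shorter-blocked mixmers). Off-target scanning is an ungapped Hamming
search (≤ 2 substitutions, T/U-equivalent) of the design's reverse
complement across a transcript set, excluding the intended site — a
deliberate simplification of k-mer web services whose exact dialect is not
reproduced.

## 4. Design engine

### Gapmer enumeration

All (length, gap, footprint offset, wing split) combinations with length
13–23, gap 7–11 and wings 3–7 (defaults) whose PS-DNA gap straddles the
junction — at least one gap residue apposing each side. Each design is the
exact reverse complement of its mutant footprint, wings in the configured
chemistry. Order is deterministic (length, gap, offset, 5′ wing);
constraints admitting no junction-straddling design yield an empty list,
not an error. Enumeration is tested against independent brute-force tuple
counting.

### Mixmer conversion

The chemistry of a design is repainted from the differential map: ASO
positions apposing `mut_accessible_wt_closed` targets become the RNA block
chemistry, everything else PS-DNA. Singleton assignments are widened to
blocks of ≥ 2, extending toward the neighbor with the larger accessibility
margin (5′-ward on ties). If no DNA run of at least `min_dna_run` (default
4) survives, RNA assignments are revoked most-3′-first until one does —
the design must stay RNase H-competent. The repaint is a pure function of
footprint and map, hence idempotent. An empty differential map returns the
design unchanged with an `empty_differential` flag. When the accessible
region is interior to the footprint the result has ≥ 2 DNA runs
(the classic mixmer rhythm); when it abuts the footprint edge — the common
geometry when the occluded segment sits immediately 5′ of the junction —
the repaint legitimately yields a single terminal RNA block, and the run
profile reports whatever is actually there.

### Mismatch variants

One variant per candidate position: ASO positions apposing `open_in_both`
targets inside the designated shared exon. The substitution is a
Watson–Crick complement swap (A↔U/T, G↔C) — the generalization of the
swaps observable in published mismatch series — which guarantees a
non-pairing apposition; chemistry is untouched and the site is recorded in
`mismatch_positions`. A substitution-matrix hook allows other schemes.

### Affinity annotation

For a design aligned ungapped to an allele with per-position accessibility
*f(m)*:

    dG_hybrid = Σ_p [ e(aso_p · target_m)  +  β(sugar_p) · f(m) ]
    dG_open   = w · Σ_m (1 − f(m))                 (w = 1 per position)
    dG_total  = dG_hybrid + dG_open

Mismatched appositions contribute a penalty of +1; β is a negative
per-residue bonus for modified sugars (LNA −0.6, 2′-MOE −0.45, 2′-OMe
−0.3) **realized in proportion to the target's accessibility** — a
modified wing buys extra affinity only where the target is actually
single-stranded. This coupling is the mechanism that makes
accessibility-guided chemistry placement allele-selective: RNA blocks
opposite mutant-open/wild-type-closed regions gain on the mutant and not on
the wild type. A purely additive score cannot distinguish two designs with
the same footprint, whatever their chemistry.

The mutant score uses the intended footprint; the wild-type score is the
best ungapped alignment within the profiled wild-type window (for a
junction-spanning design this necessarily mismatches across one half).
Gapped alignment against the un-skipped allele — modeling the intact exon
as a bulge — is out of scope. `discrimination = dG_total(wt) −
dG_total(mut)` (positive: mutant favored).

Each allele's total is also mapped to a **predicted IC50**:

    log10 IC50[nM] = 2.0 + 0.1 · (dG_total + 20),   floored at 5 nM

a log-linear potency link anchored so that a moderate duplex (−20 units)
corresponds to 100 nM, with a delivery-limited floor comparable to the
most potent transfected ASOs. The floor encodes saturation: a design whose
mutant duplex is far past the floor cannot get more potent on the mutant,
so changes are judged by how much wild-type affinity they shed. The
**predicted selectivity index** IC50(wt)/IC50(mut) is the cross-generation
comparison metric, and is what captures the empirical pattern that a
discriminating mismatch can cost the *mutant* duplex more free energy than
the wild-type one (published binding-affinity tables show exactly that)
while still improving the measured potency ratio — the loss lands on a
saturated allele. The raw free-energy difference alone moves the wrong way
in that situation, which is why ranking and the pipeline ordering use the
selectivity index.

### Pipeline and ranking

The end-to-end pipeline (`asodesign.cli.run_pipeline`) folds both windows,
builds the differential map, enumerates gapmers, and selects the reference
gapmer in two stages mirroring the experimental screen: candidates with
predicted selectivity ≥ 4 (the analog of suppressing the mutant by more
than 75% relative to wild type), then the best mutant affinity among them
(most selective candidate if none passes). That gapmer's footprint is
converted to a mixmer and scanned for mismatch variants. `rank_designs`
sorts stably by (off-target hits, discrimination descending, mutant
affinity ascending, name), so input order never changes ranks.

## 5. Assay analytics

* **2^−ΔΔCt**: `2^−[(Ct_t−Ct_ref)_treated − (Ct_t−Ct_ref)_control]`; the
  untreated control normalizes to 1 by construction, and log2 fold is
  additive in ΔΔCt (property-tested).
* **Screen**: pass ⇔ `mut_fold / wt_fold ≤ 1 − threshold`, default
  threshold 0.75 (ratio ≤ 0.25).
* **4PL fit**: decreasing logistic on log10 dose,
  `y = bottom + (top−bottom)/(1 + 10^{hill·(x − log10 IC50)})`.
  Replicates are summarized as mean ± SD per dose; when every dose has
  replicates the least-squares fit is weighted by the per-dose standard
  errors (qPCR fold-change noise is strongly heteroscedastic).
  Initialization: plateaus from the response extremes, IC50 from the dose
  nearest the half-range, hill = 1. Bounds: top ∈ [0.5, 1.5], bottom ∈
  [−0.2, 0.5], hill ∈ [0.2, 5], log10 IC50 within the dose range ± 2
  decades. At least 4 distinct doses are required. Collapsed plateaus
  (top − bottom < 0.1) or responses that rise with dose are *flagged*
  (`degenerate`, `no_inhibition`), never silently returned, and
  non-convergence is flagged rather than raised. R² is reported on the
  per-dose means.
* **Selectivity**: IC50(wt)/IC50(mut), accepting fitted curves or bare
  IC50 values; degenerate fits propagate as flags. The index is
  scale-invariant under common dose-unit rescaling.

## 6. Synthetic generators

**Locus.** Three exons; the middle one (54 nt, in-frame) is skippable. A
12-nt *occlusion segment* near the 3′ end of the upstream exon has its
reverse complement planted inside the skippable exon, so the wild-type
allele folds it closed while the mutant allele — lacking the complement —
leaves it open. Composition is chosen so this contrast is the dominant
structural signal: the occlusion is purine-rich (A/G at 0.4/0.6; its
complement is C/U-rich and exists nowhere else because the background is
C-poor, A/C/G/U at 0.45/0.10/0.33/0.12), and inert A-spacers flank the
junction (6 nt upstream — the open-in-both mismatch region — and 4 nt on
each downstream side), leaving a legal hairpin loop. Generation is seeded
and byte-identical across runs; the generator returns the planted position
set as ground truth. A hand-sized variant (`ORACLE_LOCUS`: 8+13+6 nt, G₅
occlusion against an all-A background) folds exhaustively, and the full
front half of the pipeline recovers its ground truth exactly — a
parameter-free correctness check.

What the locus does *not* emulate: realistic transcript-wide base
composition and structure (the background is deliberately under-structured
so the planted signal is unambiguous), multiple competing helices,
long-range tertiary contacts, and protein-bound regions. Passing tests on
this locus therefore demonstrate the pipeline's logic, not folding accuracy
on real mRNAs — for real targets, import externally predicted ensembles.

**Dose-response.** Seeded 4PL responses with multiplicative Gaussian noise
(`noise_sd` is a CV; additive Ct noise exponentiates into multiplicative
fold-change noise). The screening grid defaults to (10, 20, 40, 80,
100) nM; recovery studies use a 12-point two-fold ladder 0.78–1600 nM that
brackets single-digit-nanomolar potencies from below — an IC50 below the
lowest tested dose is otherwise unidentifiable. Under this protocol
(triplicates, 5% CV) the IC50 estimator's bias is ~1% and its relative SD
~0.10, so a ±15% band captures most but not all seeds (~85–90%) and a
±25% band ≥ 95% — the information limit of a free-Hill 4PL at this noise
level, which the tests assert as such.

**Design table.** The 28 published designs ship as a TSV (notation with
the `∗` and `−` glyphs preserved; a normalization layer handles
comparison). The loader parses every row, derives each mismatch position
by diffing against the parent mixmer, and attaches consistency flags where
a printed length/gap/GC value disagrees with the printed sequence itself
(three rows carry such conflicts); flagged values are kept as printed,
never corrected. Any parse failure is a hard error.

## 7. Numerical choices and degenerate inputs

Energy comparisons use a 1e-9 tolerance; the enumeration budget is keyed
on rounded budgets to keep memoization finite. Empty differential maps,
designs with no admissible placements, no mismatch candidates, and
non-inhibitory dose-response data all return empty/flagged results rather
than raising, while genuinely contradictory inputs (inverted thresholds,
inconsistent CT partner columns, sequence mismatches on import, terminal
exon skips, non-positive concentrations) raise with location information.
Stochastic components (sampling, noise) take explicit seeds everywhere;
default seeds are recorded in the objects they produce.

## 8. Known limitations

* The folding engine is a scoring model, not thermodynamics: energies are
  in model units, loop sizes beyond the minimum are unpenalized, and
  dangles/coaxial stacking are absent. It exists to drive the ss-count
  logic and to be exactly testable; plug in imported ensembles for
  realism.
* The affinity annotation and the predicted IC50 link are transparent
  analogues with fixed anchors, suitable for ordering designs, not for
  predicting absolute potency.
* Off-target scanning is ungapped and substitution-only.
* The wild-type score for junction-spanning designs uses the best ungapped
  alignment; bulged (gapped) duplex geometries are not modeled.
* SNP-in-cis targeting, pseudoknots, chemical probing integration, and
  stereochemistry are out of scope.
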