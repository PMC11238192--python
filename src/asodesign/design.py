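"""Allele-selective ASO design around an exon-skip junction.

Strategy, in the order the pipeline applies it:

1. **Gapmers** — enumerate wing/gap/wing architectures whose central PS-DNA
   gap straddles the mutant-only junction; each candidate is the reverse
   complement of its mutant footprint.
2. **Mixmer conversion** — repaint the chemistry of a candidate so that
   RNA-modified blocks sit opposite target positions that are open or
   semi-open on the mutant allele but closed on the wild-type allele; the
   rest stays PS-DNA.  A minimum DNA run is preserved so the design remains
   RNase H-competent.
3. **Mismatch variants** — substitute single bases (complement swap) at ASO
   positions apposing target positions open on *both* alleles within a
   chosen exon, trading a little affinity on both alleles for a
   disproportionate loss on the weakly bound wild-type duplex.
4. **Annotation & ranking** — score each design against both alleles with an
   accessibility-coupled hybridization model and rank.

Scoring model (model units, negative = favorable): for a design aligned
ungapped to an allele,

    dG_hybrid = Σ_pos [ pair(aso_p, target_m)  +  chem_bonus(sugar_p) · ssf(m) ]
    dG_open   = w · Σ_m (1 − ssf(m))
    dG_total  = dG_hybrid + dG_open

where ``pair`` is the per-pair score (mismatched appositions contribute a
positive penalty), ``ssf`` the allele's ss-fraction at the target position,
and ``chem_bonus`` a negative per-residue affinity bonus for modified
sugars that is only realized where the target is accessible.  On the
wild-type allele — which lacks the novel junction — the design is scored at
its best ungapped alignment within the profiled window.  ``discrimination``
is ``dG_total_wt − dG_total_mut`` (positive: mutant favored).

For ranking across design generations the annotation also maps dG to a
predicted potency: log-linear in dG with a floor (delivery-limited minimum
IC50), so a design whose mutant duplex is already far past saturation is
judged by how much *wild-type* affinity it sheds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .oligos import Backbone, OligoDesign, OligoResidue, Sugar
from .structure import DifferentialMap, SSCountProfile
from .transcripts import TranscriptPair

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_DNA_COMPLEMENT = {"A": "T", "U": "A", "T": "A", "G": "C", "C": "G"}


def _complement_residue(target_base: str, sugar: Sugar) -> str:
    if sugar is Sugar.DNA:
        return _DNA_COMPLEMENT[target_base]
    return _RNA_COMPLEMENT[target_base]


@dataclass(frozen=True)
class DesignConstraints:
    """Architecture box for gapmer enumeration and mixmer conversion."""

    length_range: tuple[int, int] = (13, 23)
    gap_range: tuple[int, int] = (7, 11)
    wing_range: tuple[int, int] = (3, 7)
    wing_chemistry: Sugar = Sugar.OME2
    rna_block_chemistry: Sugar = Sugar.OME2
    min_dna_run: int = 4
    min_block: int = 2
    junction_cover: bool = True


def _build_complement_design(
    name: str,
    target: str,
    start: int,
    length: int,
    sugars: Sequence[Sugar],
    target_name: str = "mut",
) -> OligoDesign:
    """ASO residues 5'→3' complementing ``target[start:start+length]``.

    ASO position p apposes target position ``start + length - 1 - p``.
    """
    residues = []
    for p in range(length):
        m = start + length - 1 - p
        residues.append(
            OligoResidue(
                _complement_residue(target[m], sugars[p]), sugars[p], Backbone.PS
            )
        )
    return OligoDesign(
        name=name,
        residues=tuple(residues),
        target_name=target_name,
        target_start=start,
    )


def aso_to_target_position(design: OligoDesign, p: int) -> int:
    """Target position apposed by ASO residue ``p`` (antiparallel duplex)."""
    if design.target_start is None:
        raise ValueError(f"design {design.name} has no recorded footprint")
    return design.target_start + len(design) - 1 - p


def enumerate_gapmers(
    pair: TranscriptPair, constraints: DesignConstraints | None = None
) -> list[OligoDesign]:
    """All junction-straddling wing-gap-wing designs within the constraints.

    Every admissible (length, gap, 5' footprint offset, wing split) tuple
    yields one design whose DNA gap has at least one residue on each side of
    the novel junction.  Deterministic order: length, then gap, then
    footprint offset, then 5' wing.
    """
    constraints = constraints or DesignConstraints()
    target = pair.mut_sequence
    junction = pair.mut_junction
    lmin, lmax = constraints.length_range
    gmin, gmax = constraints.gap_range
    wmin, wmax = constraints.wing_range
    out: list[OligoDesign] = []
    for length in range(lmin, lmax + 1):
        for gap in range(gmin, gmax + 1):
            for start in range(0, len(target) - length + 1):
                for w5 in range(wmin, wmax + 1):
                    w3 = length - gap - w5
                    if not wmin <= w3 <= wmax:
                        continue
                    # ASO 5' wing appears at the footprint's 3' end; the gap
                    # covers target positions [start + w3, start + w3 + gap)
                    gap_start = start + w3
                    if constraints.junction_cover and not (
                        gap_start < junction < gap_start + gap
                    ):
                        continue
                    sugars = (
                        [constraints.wing_chemistry] * w5
                        + [Sugar.DNA] * gap
                        + [constraints.wing_chemistry] * w3
                    )
                    name = f"G{length}.{gap}.{start}.{w5}"
                    out.append(
                        _build_complement_design(name, target, start, length, sugars)
                    )
    return out


def place_mixmer_chemistry(
    design: OligoDesign,
    diff: DifferentialMap,
    pair: TranscriptPair,
    constraints: DesignConstraints | None = None,
) -> OligoDesign:
    """Repaint a design's chemistry from the differential accessibility map.

    ASO positions apposing mutant-open/wild-type-closed target positions get
    the RNA block chemistry; all other positions become PS-DNA.  Single-
    position RNA assignments are widened to blocks of at least
    ``constraints.min_block``, extending toward the neighbor with the larger
    mutant-minus-wild-type accessibility margin (5'-ward on ties).  If no
    DNA run of at least ``constraints.min_dna_run`` survives, RNA
    assignments are revoked most-3' first until one does.  The repaint is a
    pure function of the footprint and the map, so applying it twice is a
    no-op.  An empty differential map returns the design unchanged, flagged
    ``empty_differential``.
    """
    constraints = constraints or DesignConstraints()
    L = len(design)
    rna = {
        p
        for p in range(L)
        if aso_to_target_position(design, p) in diff.mut_accessible_wt_closed
    }
    if not rna:
        return replace(design, flags=design.flags | {"empty_differential"})

    def margin_of(p: int) -> float:
        return diff.margin.get(aso_to_target_position(design, p), float("-inf"))

    # widen singleton (or sub-minimum) blocks toward the more accessible side
    def blocks(positions: set[int]) -> list[list[int]]:
        out: list[list[int]] = []
        for p in sorted(positions):
            if out and p == out[-1][-1] + 1:
                out[-1].append(p)
            else:
                out.append([p])
        return out

    for block in blocks(set(rna)):
        while len(block) < constraints.min_block:
            lo, hi = block[0] - 1, block[-1] + 1
            lo_ok, hi_ok = lo >= 0, hi < L
            if not lo_ok and not hi_ok:
                break
            if lo_ok and (not hi_ok or margin_of(lo) >= margin_of(hi)):
                block.insert(0, lo)
            else:
                block.append(hi)
        rna.update(block)

    def longest_dna_run(positions: set[int]) -> int:
        best = run = 0
        for p in range(L):
            run = 0 if p in positions else run + 1
            best = max(best, run)
        return best

    while rna and longest_dna_run(rna) < constraints.min_dna_run:
        rna.discard(max(rna))  # revoke the most-3' RNA assignment first

    target = pair.mut_sequence
    sugars = [
        constraints.rna_block_chemistry if p in rna else Sugar.DNA for p in range(L)
    ]
    repainted = _build_complement_design(
        design.name,
        target,
        design.target_start,
        L,
        sugars,
        target_name=design.target_name or "mut",
    )
    return replace(repainted, name=design.name, mismatch_positions=design.mismatch_positions)


def generate_mismatch_variants(
    design: OligoDesign,
    diff: DifferentialMap,
    pair: TranscriptPair,
    region: str,
) -> list[OligoDesign]:
    """One single-mismatch variant per candidate position.

    Candidates are ASO positions apposing target positions open on both
    alleles and lying inside exon ``region`` (the exon shared by both
    alleles next to the junction).  Each variant swaps that single base for
    its Watson-Crick complement (A↔U/T, G↔C), guaranteeing a non-pairing
    apposition, and records the site in ``mismatch_positions``.
    """
    start, end = pair.mut_exon_span(region)
    variants: list[OligoDesign] = []
    for p in range(len(design)):
        m = aso_to_target_position(design, p)
        if m not in diff.open_in_both or not start <= m < end:
            continue
        res = design.residues[p]
        new_base = (
            _DNA_COMPLEMENT[res.base] if res.sugar is Sugar.DNA
            else _RNA_COMPLEMENT[res.base if res.base != "T" else "U"]
        )
        residues = list(design.residues)
        residues[p] = OligoResidue(new_base, res.sugar, res.backbone)
        variants.append(
            replace(
                design,
                name=f"{design.name}.mm{p + 1}",
                residues=tuple(residues),
                mismatch_positions=design.mismatch_positions | {p},
            )
        )
    return variants


# ---------------------------------------------------------------------------
# affinity annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityParams:
    """Parameters of the accessibility-coupled hybridization score."""

    pair_scores: Mapping[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    mismatch_penalty: float = 1.0
    chem_bonus: Mapping[Sugar, float] = field(
        default_factory=lambda: {
            Sugar.LNA: -0.6,
            Sugar.MOE2: -0.45,
            Sugar.OME2: -0.3,
            Sugar.DNA: 0.0,
        }
    )
    open_weight: float = 1.0
    # dG -> predicted IC50 link: log10(IC50/nM) = ic50_log_ref +
    # ic50_slope * (dG - ic50_dg_ref), floored at ic50_floor_nM
    ic50_log_ref: float = 2.0
    ic50_dg_ref: float = -20.0
    ic50_slope: float = 0.1
    ic50_floor_nM: float = 5.0

    def pair_term(self, aso_base: str, target_base: str) -> float:
        a = "U" if aso_base == "T" else aso_base
        t = "U" if target_base == "T" else target_base
        duplex = a + t
        if duplex in ("AU", "UA", "GC", "CG", "GU", "UG"):
            kind = duplex if duplex in self.pair_scores else duplex[::-1]
            return float(self.pair_scores[kind])
        return float(self.mismatch_penalty)

    def predicted_ic50(self, dg_total: float) -> float:
        log10_ic50 = self.ic50_log_ref + self.ic50_slope * (
            dg_total - self.ic50_dg_ref
        )
        return max(self.ic50_floor_nM, float(10.0**log10_ic50))


@dataclass(frozen=True)
class AffinityAnnotation:
    """Per-allele scores for one design (model units; negative favorable)."""

    name: str
    dg_hybrid_mut: float
    dg_hybrid_wt: float
    dg_open_mut: float
    dg_open_wt: float
    wt_alignment_start: int
    ic50_pred_mut_nM: float
    ic50_pred_wt_nM: float

    @property
    def dg_total_mut(self) -> float:
        return self.dg_hybrid_mut + self.dg_open_mut

    @property
    def dg_total_wt(self) -> float:
        return self.dg_hybrid_wt + self.dg_open_wt

    @property
    def discrimination(self) -> float:
        """dG_total_wt − dG_total_mut; positive when the mutant is favored."""
        return self.dg_total_wt - self.dg_total_mut

    @property
    def selectivity_pred(self) -> float:
        """Predicted wild-type/mutant potency ratio (higher = more selective)."""
        return self.ic50_pred_wt_nM / self.ic50_pred_mut_nM


def _score_alignment(
    design: OligoDesign,
    target_seq: str,
    ssf: np.ndarray,
    start: int,
    params: AffinityParams,
) -> tuple[float, float]:
    """(dG_hybrid, dG_open) of the design apposed to target[start:start+L]."""
    L = len(design)
    hybrid = 0.0
    for p, res in enumerate(design.residues):
        m = start + L - 1 - p
        hybrid += params.pair_term(res.base, target_seq[m])
        hybrid += params.chem_bonus.get(res.sugar, 0.0) * float(ssf[m])
    open_pen = params.open_weight * float((1.0 - ssf[start : start + L]).sum())
    return hybrid, open_pen


def annotate_affinity(
    design: OligoDesign,
    pair: TranscriptPair,
    profiles: Mapping[str, SSCountProfile],
    params: AffinityParams | None = None,
) -> AffinityAnnotation:
    """Score one design against both alleles.

    ``profiles`` maps ``"mut"`` / ``"wt"`` to window ss-count profiles (with
    offsets into the respective transcripts).  The mutant score uses the
    design's intended footprint, which must lie inside the mutant profile.
    The wild-type score is the best ungapped alignment of the design within
    the wild-type window — for a junction-spanning design this necessarily
    mismatches one half.
    """
    params = params or AffinityParams()
    if design.target_start is None:
        raise ValueError(f"design {design.name} has no recorded footprint")
    mut_prof, wt_prof = profiles["mut"], profiles["wt"]
    L = len(design)
    f = design.target_start
    if not (mut_prof.offset <= f and f + L <= mut_prof.end):
        raise ValueError(
            f"design {design.name} footprint [{f}, {f + L}) outside the "
            f"profiled mutant window [{mut_prof.offset}, {mut_prof.end})"
        )

    mut_ssf = np.zeros(len(pair.mut_sequence))
    mut_ssf[mut_prof.offset : mut_prof.end] = mut_prof.ss_fraction
    hyb_mut, open_mut = _score_alignment(
        design, pair.mut_sequence, mut_ssf, f, params
    )

    wt_ssf = np.zeros(len(pair.wt_sequence))
    wt_ssf[wt_prof.offset : wt_prof.end] = wt_prof.ss_fraction
    best: tuple[float, float, int] | None = None
    for start in range(wt_prof.offset, wt_prof.end - L + 1):
        hyb, open_pen = _score_alignment(
            design, pair.wt_sequence, wt_ssf, start, params
        )
        if best is None or hyb + open_pen < best[0] + best[1]:
            best = (hyb, open_pen, start)
    if best is None:
        raise ValueError(
            f"wild-type window shorter than design {design.name}; cannot align"
        )
    hyb_wt, open_wt, wt_start = best

    return AffinityAnnotation(
        name=design.name,
        dg_hybrid_mut=hyb_mut,
        dg_hybrid_wt=hyb_wt,
        dg_open_mut=open_mut,
        dg_open_wt=open_wt,
        wt_alignment_start=wt_start,
        ic50_pred_mut_nM=params.predicted_ic50(hyb_mut + open_mut),
        ic50_pred_wt_nM=params.predicted_ic50(hyb_wt + open_wt),
    )


def rank_designs(
    designs: Sequence[OligoDesign],
    annotations: Mapping[str, AffinityAnnotation],
    off_target_hits: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Stable triage: off-target-free first, then discrimination (descending),
    then mutant affinity (ascending), then name.  Input order never changes
    the ranking."""
    rows = []
    for d in designs:
        ann = annotations[d.name]
        hits = (off_target_hits or {}).get(d.name, 0)
        rows.append(
            {
                "name": d.name,
                "notation": None,
                "length": len(d),
                "category": d.category,
                "dna_runs": "+".join(map(str, d.dna_runs)),
                "off_target_hits": hits,
                "dg_total_mut": round(ann.dg_total_mut, 3),
                "dg_total_wt": round(ann.dg_total_wt, 3),
                "discrimination": round(ann.discrimination, 3),
                "selectivity_pred": round(ann.selectivity_pred, 3),
            }
        )
    from .oligos import serialize_oligo

    for row, d in zip(rows, designs):
        row["notation"] = serialize_oligo(d)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["off_target_hits", "discrimination", "dg_total_mut", "name"],
        ascending=[True, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
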