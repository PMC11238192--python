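"""Design engine: gapmer enumeration, mixmer conversion, mismatch scan,
affinity annotation and ranking — including the headline pipeline property
that accessibility-guided chemistry and a single mismatch each buy a strict
gain in predicted allele selectivity."""

from dataclasses import replace

import numpy as np
import pytest

import asodesign as ad
from asodesign.design import (
    AffinityParams,
    DesignConstraints,
    annotate_affinity,
    aso_to_target_position,
    enumerate_gapmers,
    generate_mismatch_variants,
    place_mixmer_chemistry,
    rank_designs,
)
from asodesign.oligos import Sugar
from asodesign.structure import DifferentialMap, SSCountProfile
from asodesign.transcripts import Exon, build_junction_pair

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@pytest.fixture(scope="module")
def big_pair():
    pair, _ = ad.generate_synthetic_locus()
    return pair


def brute_force_gapmer_tuples(pair, c: DesignConstraints):
    """Independent enumeration of admissible (length, gap, start, w5)."""
    out = []
    j = pair.mut_junction
    n = len(pair.mut_sequence)
    for length in range(c.length_range[0], c.length_range[1] + 1):
        for gap in range(c.gap_range[0], c.gap_range[1] + 1):
            for w5 in range(c.wing_range[0], c.wing_range[1] + 1):
                w3 = length - gap - w5
                if not c.wing_range[0] <= w3 <= c.wing_range[1]:
                    continue
                for start in range(0, n - length + 1):
                    gs = start + w3
                    if gs < j < gs + gap:
                        out.append((length, gap, start, w5))
    return sorted(out)


def test_enumeration_count_matches_brute_force(big_pair):
    constraints = DesignConstraints()
    designs = enumerate_gapmers(big_pair, constraints)
    expected = brute_force_gapmer_tuples(big_pair, constraints)

    def w5_of(d):  # 5' wing length = leading non-DNA run
        for p, r in enumerate(d.residues):
            if r.sugar is Sugar.DNA:
                return p
        return len(d)

    got = sorted(
        (len(d), max(d.dna_runs), d.target_start, w5_of(d)) for d in designs
    )
    assert got == expected


def test_enumeration_deterministic_order(big_pair):
    a = enumerate_gapmers(big_pair)
    b = enumerate_gapmers(big_pair)
    assert [d.name for d in a] == [d.name for d in b]
    keys = [(len(d), max(d.dna_runs), d.target_start) for d in a]
    assert keys == sorted(keys)


def test_gap_straddles_junction_and_design_is_reverse_complement(big_pair):
    j = big_pair.mut_junction
    for d in enumerate_gapmers(
        big_pair, DesignConstraints(length_range=(13, 15))
    ):
        start, end = d.footprint
        assert start < j < end
        # DNA gap straddles: at least one DNA residue apposing each side
        gap_targets = [
            aso_to_target_position(d, p)
            for p, r in enumerate(d.residues)
            if r.sugar is Sugar.DNA
        ]
        assert min(gap_targets) < j <= max(gap_targets)
        # perfect Watson-Crick apposition over the whole footprint
        for p, r in enumerate(d.residues):
            m = aso_to_target_position(d, p)
            base = "U" if r.base == "T" else r.base
            assert WC[big_pair.mut_sequence[m]] == base


def test_impossible_constraints_give_empty_list(big_pair):
    tight = DesignConstraints(length_range=(13, 13), gap_range=(11, 11))
    assert enumerate_gapmers(big_pair, tight) == []


# ---------------------------------------------------------------------------
# mixmer chemistry placement
# ---------------------------------------------------------------------------

def _toy_pair():
    return build_junction_pair(
        [Exon("A", "A" * 30), Exon("B", "C" * 9), Exon("C", "G" * 30)], 1
    )


def _diff(selected, margin=None, open_both=frozenset()):
    return DifferentialMap(
        mut_accessible_wt_closed=frozenset(selected),
        open_in_both=frozenset(open_both),
        margin=margin or {},
    )


def test_empty_differential_returns_design_unchanged_with_flag(big_pair):
    d = enumerate_gapmers(big_pair)[0]
    out = place_mixmer_chemistry(d, _diff([]), big_pair)
    assert out.residues == d.residues
    assert "empty_differential" in out.flags


def test_rna_blocks_land_opposite_differential_positions():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(17, 17), gap_range=(7, 7))
    )[0]
    start, end = d.footprint
    selected = {start + 2, start + 3, start + 4}
    out = place_mixmer_chemistry(d, _diff(selected), pair)
    for p, r in enumerate(out.residues):
        m = aso_to_target_position(out, p)
        if m in selected:
            assert r.sugar is Sugar.OME2
    assert out.dna_runs and max(out.dna_runs) >= 4
    assert len(out.dna_runs) >= 2  # interior block splits the DNA


def test_singleton_assignment_widened_to_min_block():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(17, 17), gap_range=(7, 7))
    )[0]
    start, _ = d.footprint
    lone = start + 5
    margin = {lone: 0.9, lone - 1: 0.8, lone + 1: 0.1}
    out = place_mixmer_chemistry(d, _diff({lone}, margin), pair)
    rna_targets = {
        aso_to_target_position(out, p)
        for p, r in enumerate(out.residues)
        if r.sugar is not Sugar.DNA
    }
    assert {lone, lone - 1} <= rna_targets  # widened toward the higher margin


def test_min_dna_run_preserved_by_revocation():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(13, 13), gap_range=(7, 7))
    )[0]
    start, end = d.footprint
    out = place_mixmer_chemistry(d, _diff(set(range(start, end))), pair)
    assert out.dna_runs and max(out.dna_runs) >= 4


def test_placement_idempotent(big_pair, default_pipeline):
    diff = default_pipeline["differential"]
    d = default_pipeline["best_gapmer"]
    once = place_mixmer_chemistry(d, diff, big_pair)
    twice = place_mixmer_chemistry(once, diff, big_pair)
    assert once.residues == twice.residues


# ---------------------------------------------------------------------------
# mismatch variants
# ---------------------------------------------------------------------------

def test_variants_one_per_candidate_with_complement_swap():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(17, 17), gap_range=(7, 7))
    )[0]
    start, _ = d.footprint
    exon_a_end = pair.mut_exon_span("A")[1]
    candidates = {start + 1, start + 2, exon_a_end - 1}
    variants = generate_mismatch_variants(
        d, _diff([], open_both=candidates), pair, region="A"
    )
    assert len(variants) == len(candidates)
    for v in variants:
        diffs = [
            p
            for p, (a, b) in enumerate(zip(d.residues, v.residues))
            if a.base != b.base
        ]
        assert len(diffs) == 1
        (p,) = diffs
        assert v.mismatch_positions == frozenset({p})
        assert v.category == "mismatch_mixmer"
        old = "U" if d.residues[p].base == "T" else d.residues[p].base
        new = "U" if v.residues[p].base == "T" else v.residues[p].base
        assert WC[old] == new
        assert v.residues[p].sugar is d.residues[p].sugar


def test_no_candidates_empty_list():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(13, 13), gap_range=(7, 7))
    )[0]
    assert generate_mismatch_variants(d, _diff([]), pair, region="A") == []


# ---------------------------------------------------------------------------
# affinity annotation
# ---------------------------------------------------------------------------

def _flat_profiles(pair, mut_frac=1.0, wt_frac=1.0, n=30):
    return {
        "mut": SSCountProfile(
            tuple(int(round(mut_frac * n)) for _ in pair.mut_sequence), n
        ),
        "wt": SSCountProfile(
            tuple(int(round(wt_frac * n)) for _ in pair.wt_sequence), n
        ),
    }


def test_internal_mismatch_strictly_less_favorable():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(15, 15), gap_range=(7, 7))
    )[0]
    profiles = _flat_profiles(pair)
    clean = annotate_affinity(d, pair, profiles)
    res = list(d.residues)
    p = 0  # a 2'-OMe wing residue
    swapped = WC["U" if res[p].base == "T" else res[p].base]
    res[p] = replace(res[p], base=swapped)
    mismatched = replace(d, name="mm", residues=tuple(res))
    dirty = annotate_affinity(mismatched, pair, profiles)
    assert dirty.dg_total_mut > clean.dg_total_mut


def test_open_footprint_strictly_better_than_closed():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(15, 15), gap_range=(7, 7))
    )[0]
    open_prof = _flat_profiles(pair, mut_frac=1.0)
    closed_prof = _flat_profiles(pair, mut_frac=0.0)
    a_open = annotate_affinity(d, pair, open_prof)
    a_closed = annotate_affinity(d, pair, closed_prof)
    assert a_open.dg_total_mut < a_closed.dg_total_mut


def test_junction_spanning_design_favors_mutant(oracle_products):
    """On the tiny locus, a design straddling the novel junction binds the
    mutant more favorably than the wild-type (positive discrimination)."""
    pair = oracle_products["pair"]
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(13, 14), gap_range=(7, 8),
                                wing_range=(3, 4))
    )[0]
    ann = annotate_affinity(d, pair, oracle_products["profiles"])
    assert ann.discrimination > 0
    assert ann.ic50_pred_mut_nM < ann.ic50_pred_wt_nM


def test_footprint_outside_profiled_window_rejected():
    pair = _toy_pair()
    d = enumerate_gapmers(
        pair, DesignConstraints(length_range=(15, 15), gap_range=(7, 7))
    )[0]
    short = {
        "mut": SSCountProfile((30,) * 5, 30, offset=0),
        "wt": SSCountProfile((30,) * len(pair.wt_sequence), 30),
    }
    with pytest.raises(ValueError, match="outside"):
        annotate_affinity(d, pair, short)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_ranking_single_and_off_target_priority(default_pipeline):
    designs = default_pipeline["gapmers"][:2]
    anns = {d.name: default_pipeline["annotations"][d.name] for d in designs}
    solo = rank_designs(designs[:1], anns)
    assert list(solo["rank"]) == [1]
    dirty_hits = {designs[0].name: 3, designs[1].name: 0}
    table = rank_designs(designs, anns, dirty_hits)
    assert table.iloc[0]["name"] == designs[1].name


def test_ranking_permutation_invariant(default_pipeline):
    designs = list(default_pipeline["gapmers"][:12])
    anns = default_pipeline["annotations"]
    fwd = rank_designs(designs, anns)
    rev = rank_designs(designs[::-1], anns)
    assert list(fwd["name"]) == list(rev["name"])


# ---------------------------------------------------------------------------
# the pipeline ordering property
# ---------------------------------------------------------------------------

def test_pipeline_selectivity_ordering(default_pipeline):
    """gapmer < mixmer < mismatch-mixmer in predicted allele selectivity on
    the packaged synthetic locus: accessibility-guided RNA placement and a
    single discriminating mismatch each strictly improve the predicted
    wild-type/mutant potency ratio."""
    ann = default_pipeline["annotations"]
    gapmer = default_pipeline["best_gapmer"]
    mixmer = default_pipeline["mixmer"]
    variants = default_pipeline["mismatch_variants"]
    assert variants, "mismatch scan found no candidate positions"
    sel_gap = ann[gapmer.name].selectivity_pred
    sel_mix = ann[mixmer.name].selectivity_pred
    sel_best_var = max(ann[v.name].selectivity_pred for v in variants)
    assert sel_gap < sel_mix < sel_best_var
    # mutant-side efficacy is retained along the way (saturated potency)
    assert ann[mixmer.name].ic50_pred_mut_nM <= ann[gapmer.name].ic50_pred_mut_nM + 1e-9


def test_pipeline_differential_recovers_planted_occlusion(default_pipeline):
    truth = default_pipeline["truth"]
    found = default_pipeline["differential"].mut_accessible_wt_closed
    assert len(found & truth) >= len(truth) // 2
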