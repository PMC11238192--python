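"""Folding engine, ss-count and accessibility classification.

The deepest check is oracle equivalence: the engine's exhaustive mode must
return exactly the structure set found by an independent brute-force
enumerator over all nested pairings, under the same energy definition.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import asodesign as ad
from asodesign.structure import (
    CANONICAL_PAIRS,
    AccessClass,
    FoldConfig,
    SecondaryStructure,
    SSCountProfile,
    StructureEnsemble,
    consensus_class,
    export_heatmap_table,
    structure_energy,
)


def brute_force_structures(seq: str, config: FoldConfig) -> set[tuple[int, ...]]:
    """All nested pairings, by incremental pair-set extension (independent
    of the engine's interval decomposition)."""
    n = len(seq)
    cand = [
        (i, j)
        for i in range(n)
        for j in range(i + config.min_loop + 1, n)
        if seq[i] + seq[j] in CANONICAL_PAIRS
    ]
    found: set[frozenset] = set()

    def rec(idx: int, chosen: frozenset, used: frozenset) -> None:
        found.add(chosen)
        for t in range(idx, len(cand)):
            i, j = cand[t]
            if i in used or j in used:
                continue
            if any((a < i < b < j) or (i < a < j < b) for a, b in chosen):
                continue
            rec(t + 1, chosen | {(i, j)}, used | {i, j})

    rec(0, frozenset(), frozenset())
    out = set()
    for pairs in found:
        pairing = [-1] * n
        for i, j in pairs:
            pairing[i], pairing[j] = j, i
        out.add(tuple(pairing))
    return out


def test_unpairable_sequence_yields_single_open_structure():
    ens = ad.fold_ensemble("AAAA")
    assert ens.n_structures == 1
    assert ens.structures[0].pairing == (-1, -1, -1, -1)
    assert ens.structures[0].energy == 0.0


def test_hairpin_optimum_pairs_the_stem():
    ens = ad.fold_ensemble("GGGAAAACCC")
    optimum = min(ens.structures, key=lambda s: s.energy)
    assert optimum.pairs == {(0, 9), (1, 8), (2, 7)}


@pytest.mark.parametrize("seed", range(4))
def test_exhaustive_mode_matches_brute_force_oracle(seed):
    """Engine structure sets equal brute-force enumeration within the band,
    with identical energies, over random short sequences."""
    rng = np.random.default_rng(seed)
    config = FoldConfig()
    for _ in range(6):
        n = int(rng.integers(6, 14))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        ens = ad.fold_ensemble(seq, config)
        all_pairings = brute_force_structures(seq, config)
        energies = {p: structure_energy(p, seq, config) for p in all_pairings}
        emin = min(energies.values())
        oracle = {
            p for p, e in energies.items() if e <= emin + config.energy_band + 1e-9
        }
        assert {s.pairing for s in ens.structures} == oracle
        for s in ens.structures:
            assert s.energy == pytest.approx(energies[s.pairing])
            s.validate(seq, config.min_loop)


def test_sampled_mode_is_seeded_and_contains_optimum():
    seq = "GGGAAAACCCAAAGGGAAAACCCAAAGGG"  # > exhaustive cutoff
    a = ad.fold_ensemble(seq, FoldConfig(seed=11))
    b = ad.fold_ensemble(seq, FoldConfig(seed=11))
    c = ad.fold_ensemble(seq, FoldConfig(seed=12))
    assert [s.pairing for s in a.structures] == [s.pairing for s in b.structures]
    assert a.n_structures == 30
    assert any(
        s.pairing != t.pairing for s, t in zip(a.structures, c.structures)
    )
    emin = min(s.energy for s in a.structures)
    config = FoldConfig(seed=11)
    for s in a.structures:
        s.validate(seq, config.min_loop)
        assert s.energy == pytest.approx(structure_energy(s.pairing, seq, config))
    # a stacked full stem is the optimum here; the sample must contain it
    assert emin < 0


def test_invalid_alphabet_rejected():
    with pytest.raises(ValueError):
        ad.fold_ensemble("ACGX")


# ---------------------------------------------------------------------------
# ss-count
# ---------------------------------------------------------------------------

random_ensembles = st.integers(0, 10_000)


@given(random_ensembles)
@settings(max_examples=30, deadline=None)
def test_ss_count_equals_direct_tally_and_conserves(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 16))
    seq = "".join(rng.choice(list("ACGU"), size=n))
    ens = ad.fold_ensemble(seq, FoldConfig(energy_band=4.0))
    profile = ad.compute_ss_count(ens)
    tally = [
        sum(1 for s in ens.structures if s.pairing[i] < 0) for i in range(n)
    ]
    assert list(profile.ss_count) == tally
    total_unpaired = sum(
        int(s.unpaired_mask().sum()) for s in ens.structures
    )
    assert sum(profile.ss_count) == total_unpaired
    assert np.all(profile.ss_fraction >= 0) and np.all(profile.ss_fraction <= 1)


def test_ss_count_extremes():
    open_s = SecondaryStructure((-1, -1, -1, -1, -1, -1, -1, -1, -1, -1), 0.0)
    paired = SecondaryStructure((9, 8, 7, -1, -1, -1, -1, 2, 1, 0), -6.0)
    ens = StructureEnsemble("GGGAAAACCC", tuple([open_s] * 20 + [paired] * 10))
    profile = ad.compute_ss_count(ens)
    assert profile.n_structures == 30
    assert profile.ss_count[3] == 30  # unpaired everywhere
    assert profile.ss_count[0] == 20  # paired in 10 of 30


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _profile(fracs, n=30):
    return SSCountProfile(tuple(int(round(f * n)) for f in fracs), n)


def test_classification_extremes_and_default_thresholds():
    amap = ad.classify_accessibility(_profile([1.0, 0.0, 0.5]))
    assert amap.classes[0] is AccessClass.OPEN
    assert amap.classes[1] is AccessClass.CLOSED
    assert amap.classes[2] is AccessClass.SEMI_OPEN


def test_classification_boundary_is_inclusive():
    amap = ad.classify_accessibility(_profile([2 / 3, 1 / 3], n=3))
    assert amap.classes[0] is AccessClass.OPEN
    assert amap.classes[1] is AccessClass.CLOSED


def test_inverted_thresholds_rejected():
    with pytest.raises(ValueError):
        ad.classify_accessibility(_profile([0.5]), thresholds=(0.3, 0.7))


@given(st.lists(st.integers(0, 30), min_size=1, max_size=40))
@settings(max_examples=50, deadline=None)
def test_classification_monotone_in_ss_fraction(counts):
    """Raising ss-fraction never moves a position toward closed."""
    order = {AccessClass.CLOSED: 0, AccessClass.SEMI_OPEN: 1, AccessClass.OPEN: 2}
    profile = SSCountProfile(tuple(counts), 30)
    amap = ad.classify_accessibility(profile)
    bumped = SSCountProfile(tuple(min(c + 3, 30) for c in counts), 30)
    bmap = ad.classify_accessibility(bumped)
    for a, b in zip(amap.classes, bmap.classes):
        assert order[b] >= order[a]


# ---------------------------------------------------------------------------
# differential map
# ---------------------------------------------------------------------------

def test_identical_profiles_give_empty_selective_set(oracle_products):
    pair = oracle_products["pair"]
    mm = oracle_products["maps"]["mut"]
    # compare the mutant against itself through the identity part of the map
    diff = ad.differential_accessibility(mm, mm, _identity_pair(pair), None)
    assert diff.mut_accessible_wt_closed == frozenset()


def _identity_pair(pair):
    """A no-skip pair (mut == wt) over the mutant sequence."""
    from asodesign.transcripts import TranscriptPair

    return TranscriptPair(
        wt_sequence=pair.mut_sequence,
        mut_sequence=pair.mut_sequence,
        wt_junction=pair.mut_junction,
        mut_junction=pair.mut_junction,
        skipped_length=0,
        skipped_exon_id="none",
        skipped_sequence="",
        in_frame=True,
        wt_exon_spans=pair.mut_exon_spans,
        mut_exon_spans=pair.mut_exon_spans,
    )


def test_oracle_locus_differential_matches_ground_truth(oracle_products):
    """On the hand-sized locus the planted occlusion is recovered exactly."""
    diff = oracle_products["diff"]
    assert diff.mut_accessible_wt_closed == oracle_products["truth"]


def test_region_filter_excludes_downstream_exon(oracle_products):
    pair = oracle_products["pair"]
    diff = ad.differential_accessibility(
        oracle_products["maps"]["mut"],
        oracle_products["maps"]["wt"],
        pair,
        region="exonA",
    )
    start, end = pair.mut_exon_span("exonA")
    assert all(start <= p < end for p in diff.open_in_both)


def test_disjoint_sets_invariant(oracle_products):
    diff = oracle_products["diff"]
    assert not diff.mut_accessible_wt_closed & diff.open_in_both


def test_non_overlapping_windows_rejected(oracle_products):
    pair = oracle_products["pair"]
    mm = oracle_products["maps"]["mut"]
    from dataclasses import replace

    far = replace(oracle_products["maps"]["wt"], offset=10_000)
    with pytest.raises(ValueError):
        ad.differential_accessibility(mm, far, pair)


# ---------------------------------------------------------------------------
# heatmap export
# ---------------------------------------------------------------------------

def test_consensus_majority_and_tie_rules():
    o, s, c = AccessClass.OPEN, AccessClass.SEMI_OPEN, AccessClass.CLOSED
    assert consensus_class([o]) is o
    assert consensus_class([o, o, o, o, c, c]) is o
    assert consensus_class([o, o, o, c, c, c]) is s


def test_heatmap_table_columns_and_consensus(tmp_path):
    seq = "GGGAAAACCC"
    profiles = {
        10: SSCountProfile((30,) * 10, 30),
        6: SSCountProfile((0,) * 6, 30, offset=2),
    }
    out = tmp_path / "heatmap.tsv"
    table = export_heatmap_table(seq, profiles, path=out)
    assert list(table["position"]) == list(range(10))
    row0 = table[table["position"] == 0].iloc[0]
    assert row0["class_10"] == "open" and row0["consensus"] == "open"
    row3 = table[table["position"] == 3].iloc[0]
    assert row3["class_6"] == "closed" and row3["consensus"] == "semi_open"
    assert out.exists()
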