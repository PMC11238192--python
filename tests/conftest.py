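"""Shared fixtures: the packaged design table, the tiny exhaustively foldable
locus with its accessibility products, and the full pipeline run on the
default synthetic locus (session-scoped — folding is the expensive step)."""

from __future__ import annotations

import warnings

import pytest

import asodesign as ad
from asodesign.cli import run_pipeline


@pytest.fixture(scope="session")
def design_table():
    return ad.load_design_table()


@pytest.fixture(scope="session")
def oracle_locus():
    pair, truth = ad.generate_synthetic_locus(ad.ORACLE_LOCUS)
    return pair, truth


@pytest.fixture(scope="session")
def oracle_products(oracle_locus):
    """Exhaustive-mode accessibility products for the hand-sized locus."""
    pair, truth = oracle_locus
    mut_ens = ad.fold_ensemble(pair.mut_sequence)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt_windows = ad.extract_centered_windows(pair, [24])[24]
    wt_win = wt_windows["wt"]
    wt_ens = ad.fold_ensemble(wt_win.sequence)
    mut_prof = ad.compute_ss_count(mut_ens, offset=0)
    wt_prof = ad.compute_ss_count(wt_ens, offset=wt_win.offset)
    mut_map = ad.classify_accessibility(mut_prof)
    wt_map = ad.classify_accessibility(wt_prof)
    diff = ad.differential_accessibility(mut_map, wt_map, pair)
    return {
        "pair": pair,
        "truth": truth,
        "profiles": {"mut": mut_prof, "wt": wt_prof},
        "maps": {"mut": mut_map, "wt": wt_map},
        "diff": diff,
    }


@pytest.fixture(scope="session")
def default_pipeline():
    """End-to-end pipeline on the packaged default locus and fold seed."""
    pair, truth = ad.generate_synthetic_locus()
    result = run_pipeline(pair, region="exonA")
    result["truth"] = truth
    return result
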