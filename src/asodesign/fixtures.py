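"""Packaged design-table fixture and synthetic input generators.

Everything the pipeline consumes can be produced here without a download:

* the packaged table of 28 published junction-targeting designs (classical
  gapmers, accessibility-guided mixmers and single-mismatch mixmers), with
  per-row consistency flags comparing the printed metadata columns against
  the parsed sequences;
* a synthetic exon-skip locus whose wild-type allele folds back on itself —
  an *occlusion* segment at the 3' end of the upstream exon pairs with its
  reverse complement inside the skippable exon — so that skipping the exon
  opens the segment on the mutant allele only.  This operationalizes the
  "open on mutant, closed on wild-type" signal the mixmer design rule needs,
  with known ground truth;
* synthetic 4PL dose-response tables in the assay module's input dialect.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .oligos import OligoDesign, gc_content, parse_oligo_notation
from .transcripts import Exon, TranscriptPair, build_junction_pair

# ---------------------------------------------------------------------------
# packaged design table
# ---------------------------------------------------------------------------

#: reported IC50 values (nM) per design and allele, as published; these are
#: assay inputs for selectivity arithmetic, not computed quantities.
REPORTED_IC50_NM: dict[str, dict[str, float]] = {
    "M-1": {"mut": 25.0, "wt": 130.0},
    "M-2": {"mut": 13.0, "wt": 103.0},
    "M-7": {"mut": 7.0, "wt": 83.0},
    "MM(1-7)": {"mut": 8.0, "wt": 261.0},
    "2'-OMe-2": {"wt": 25.5},
}

MISMATCH_PARENT = "M-7"


def _normalize_number(text: str) -> float:
    """Parse a printed number, tolerating the Unicode minus glyph."""
    return float(unicodedata.normalize("NFKC", text).replace("−", "-"))


@dataclass(frozen=True)
class DesignTableRecord:
    name: str
    printed_category: str
    notation: str
    design: OligoDesign
    printed_length: int
    printed_dna_gap: int
    printed_gc_percent: float
    printed_tm_c: float
    printed_off_target: bool
    printed_dg_mut: float
    printed_dg_wt: float
    consistency_flags: frozenset[str] = frozenset()

    @property
    def consistent(self) -> bool:
        return not self.consistency_flags


@dataclass(frozen=True)
class DesignTableFixture:
    records: tuple[DesignTableRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) != 28:
            raise ValueError(f"expected 28 records, got {len(self.records)}")

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> DesignTableRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.printed_category] = counts.get(rec.printed_category, 0) + 1
        return counts


def _consistency_flags(
    design: OligoDesign, length: int, gap: int, gc: float
) -> frozenset[str]:
    flags = set()
    if len(design) != length:
        flags.add("length_mismatch")
    runs = design.dna_runs
    if (max(runs) if runs else 0) != gap:
        flags.add("gap_mismatch")
    if abs(gc_content(design) - gc) > 0.05:
        flags.add("gc_mismatch")
    return frozenset(flags)


def load_design_table() -> DesignTableFixture:
    """Load and validate the packaged table of 28 published designs.

    Every row is parsed from its notation; mismatch-mixmer rows derive their
    mismatch position by comparison with the parent mixmer.  Printed
    metadata that disagrees with the parsed sequence is flagged per row, not
    silently corrected.  Any parse failure is a hard error — the fixture
    must be internally sound.
    """
    path = resources.files("asodesign.data") / "aso_design_table.tsv"
    with path.open(encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))

    designs: dict[str, OligoDesign] = {}
    for row in rows:
        designs[row["name"]] = parse_oligo_notation(row["notation"], name=row["name"])

    parent = designs.get(MISMATCH_PARENT)
    records = []
    for row in rows:
        design = designs[row["name"]]
        if row["printed_category"] == "mismatch_mixmer":
            if parent is None or len(parent) != len(design):
                raise ValueError(
                    f"{row['name']}: no parent design to derive the mismatch from"
                )
            diffs = frozenset(
                i
                for i, (a, b) in enumerate(zip(parent.sequence, design.sequence))
                if a != b
            )
            if len(diffs) != 1:
                raise ValueError(
                    f"{row['name']}: expected exactly one base difference from "
                    f"{MISMATCH_PARENT}, found {sorted(diffs)}"
                )
            design = OligoDesign(
                name=design.name,
                residues=design.residues,
                mismatch_positions=diffs,
            )
        length = int(row["length"])
        gap = int(row["dna_gap"])
        gc = _normalize_number(row["gc_percent"])
        records.append(
            DesignTableRecord(
                name=row["name"],
                printed_category=row["printed_category"],
                notation=row["notation"],
                design=design,
                printed_length=length,
                printed_dna_gap=gap,
                printed_gc_percent=gc,
                printed_tm_c=_normalize_number(row["tm_c"]),
                printed_off_target=row["off_target"].strip().lower() == "yes",
                printed_dg_mut=_normalize_number(row["dg_mut_kcal"]),
                printed_dg_wt=_normalize_number(row["dg_wt_kcal"]),
                consistency_flags=_consistency_flags(design, length, gap, gc),
            )
        )
    return DesignTableFixture(tuple(records))


# ---------------------------------------------------------------------------
# synthetic exon-skip locus
# ---------------------------------------------------------------------------

#: background composition is C-poor and the occluded segment purine-rich, so
#: the segment's only strong complement is the one planted in the skippable
#: exon — spurious helices elsewhere stay short and unstable
_BACKGROUND_BASES = np.array(list("ACGU"))
_BACKGROUND_WEIGHTS = np.array([0.45, 0.10, 0.33, 0.12])
_OCCLUSION_WEIGHTS = np.array([0.40, 0.00, 0.60, 0.00])


@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Geometry of the synthetic three-exon exon-skip locus.

    ``occlusion`` is the half-open interval (in upstream-exon coordinates)
    designed to base-pair with the skippable exon on the wild-type allele;
    the skippable exon carries its reverse complement.  Defaults model a
    54-nt in-frame skippable exon flanked by exons of realistic intron-free
    span, with a 12-nt occluded segment ending 6 nt before the junction so
    that a short open-in-both region remains next to the junction.
    """

    exon_a_length: int = 120
    skipped_length: int = 54
    exon_b_length: int = 90
    occlusion: tuple[int, int] = (102, 114)
    occlusion_sequence: str | None = None
    seed: int = 7

    def __post_init__(self) -> None:
        start, end = self.occlusion
        if not 0 <= start < end <= self.exon_a_length:
            raise ValueError(
                f"occlusion {self.occlusion} outside the upstream exon "
                f"[0, {self.exon_a_length})"
            )
        if self.skipped_length < (end - start) + 8:
            raise ValueError("skippable exon too short to host the occlusion")

    @property
    def in_frame(self) -> bool:
        return self.skipped_length % 3 == 0


#: a hand-sized locus whose evaluation windows fold exhaustively: the
#: occluded G-run pairs a C-run in the skippable exon and nothing else pairs
ORACLE_LOCUS = SyntheticLocusSpec(
    exon_a_length=8,
    skipped_length=13,
    exon_b_length=6,
    occlusion=(3, 8),
    occlusion_sequence="GGGGG",
    seed=0,
)


def generate_synthetic_locus(
    spec: SyntheticLocusSpec | None = None,
) -> tuple[TranscriptPair, frozenset[int]]:
    """Build the locus and return the pair plus the ground-truth open set.

    The returned position set (mutant-transcript coordinates) is where the
    design rule *should* detect mutant-accessible / wild-type-closed
    structure: exactly the occluded segment, which is base-paired on the
    wild-type allele and has no pairing partner once the exon is skipped.
    Generation is seeded and byte-identical across runs.
    """
    spec = spec or SyntheticLocusSpec()
    rng = np.random.default_rng(spec.seed)
    start, end = spec.occlusion
    occ_len = end - start

    def background(n: int) -> str:
        if spec.occlusion_sequence is not None:
            # oracle-style loci use an inert A background: no spurious pairs
            return "A" * n
        return "".join(rng.choice(_BACKGROUND_BASES, size=n, p=_BACKGROUND_WEIGHTS))

    occ = spec.occlusion_sequence or "".join(
        rng.choice(_BACKGROUND_BASES, size=occ_len, p=_OCCLUSION_WEIGHTS)
    )
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    occ_rc = "".join(comp[b] for b in reversed(occ))

    # unstructured A spacers flank the junction on both sides: they stay
    # single-stranded on both alleles (the open-in-both mismatch region) and
    # leave a legal hairpin loop between the occlusion and its complement
    exon_a = background(start) + occ + "A" * (spec.exon_a_length - end)
    pad = spec.skipped_length - occ_len - 4
    exon_b = "A" * 4 + occ_rc + background(pad)
    exon_c = "A" * min(4, spec.exon_b_length) + background(
        max(spec.exon_b_length - 4, 0)
    )

    pair = build_junction_pair(
        [Exon("exonA", exon_a), Exon("exonB", exon_b), Exon("exonC", exon_c)],
        skip_index=1,
    )
    # the occluded segment sits left of the junction: mutant coordinates
    # equal upstream-exon coordinates
    return pair, frozenset(range(start, end))


# ---------------------------------------------------------------------------
# synthetic dose-response tables
# ---------------------------------------------------------------------------

#: the screening concentration grid (nM)
DEFAULT_DOSES_NM = (10.0, 20.0, 40.0, 80.0, 100.0)

#: 12-point two-fold dilution ladder (0.78 - 1600 nM) used for IC50
#: recovery studies: it brackets single-digit-nanomolar potencies from below
RECOVERY_DOSES_NM = tuple(0.78125 * 2.0**k for k in range(12))


@dataclass(frozen=True)
class DoseResponseParams:
    top: float = 1.0
    bottom: float = 0.0
    ic50_nM: float = 10.0
    hill: float = 1.0


def generate_dose_response(
    params: DoseResponseParams,
    design: str = "ASO",
    allele: str = "mut",
    doses_nM: Sequence[float] = DEFAULT_DOSES_NM,
    replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded 4PL responses with Gaussian noise, one row per
    (dose, replicate), in the dose-table dialect the assay module reads.

    ``noise_sd`` is a coefficient of variation: the noise scales with the
    clean response, matching the multiplicative error structure of
    qPCR-derived fold-changes (additive Ct noise exponentiates).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses_nM:
        clean = params.bottom + (params.top - params.bottom) / (
            1.0 + (dose / params.ic50_nM) ** params.hill
        )
        for rep in range(1, replicates + 1):
            noisy = clean * (1.0 + rng.normal(0.0, noise_sd)) if noise_sd else clean
            rows.append(
                {
                    "design": design,
                    "allele": allele,
                    "dose_nM": float(dose),
                    "replicate": rep,
                    "fold_change": float(noisy),
                }
            )
    return pd.DataFrame(rows)
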