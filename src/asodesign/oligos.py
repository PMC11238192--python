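"""Chemically modified antisense oligonucleotides (ASOs).

An ASO is a 5'→3' list of residues, each with a base, a sugar chemistry and
a backbone linkage.  The text notation mirrors how gapmer/mixmer designs
are written in the field:

* ``[...]``  — 2'-O-methyl (2'-OMe) residues,
* ``<...>``  — 2'-O-methoxyethyl (2'-MOE) residues,
* ``{...}``  — locked nucleic acid (LNA) residues,
* ``B∗`` (or ``B*``) — a phosphorothioate DNA residue.

DNA residues are written with T; 2'-OMe / 2'-MOE ribose residues with U;
LNA residues may carry either.  Architecture vocabulary: a *gapmer* has a
single central DNA run (the RNase H-recruiting "gap") flanked by modified
wings; a *mixmer* interleaves two or more DNA runs with modified RNA
blocks; a *mismatch mixmer* additionally carries one or more deliberate
non-complementary bases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

PS_STAR = "∗"  # the ∗ glyph used in design tables


class Sugar(str, Enum):
    DNA = "DNA"
    OME2 = "2'-OMe"
    MOE2 = "2'-MOE"
    LNA = "LNA"


class Backbone(str, Enum):
    PS = "PS"
    PO = "PO"


_BRACKETS: dict[str, tuple[str, Sugar]] = {
    "[": ("]", Sugar.OME2),
    "<": (">", Sugar.MOE2),
    "{": ("}", Sugar.LNA),
}
_CLOSERS = {close for close, _ in _BRACKETS.values()}


@dataclass(frozen=True)
class OligoResidue:
    base: str
    sugar: Sugar
    backbone: Backbone = Backbone.PS

    def __post_init__(self) -> None:
        if self.base not in "ACGTU":
            raise ValueError(f"invalid base {self.base!r}")
        if self.sugar is Sugar.DNA and self.base == "U":
            raise ValueError("DNA residues use T, not U")
        if self.sugar is Sugar.OME2 and self.base == "T":
            raise ValueError("2'-OMe residues use U, not T")
        # 2'-MOE and LNA are written with either T (5-methyl-U) or U


@dataclass(frozen=True)
class OligoDesign:
    """A named ASO design: residues plus target bookkeeping.

    ``target_start`` is the 0-based start of the design's footprint on its
    target transcript (mutant-allele coordinates for junction designs); the
    design is the reverse complement of that footprint.  ``mismatch_positions``
    are 5'→3' residue indices deliberately not complementary to the target.
    """

    name: str
    residues: tuple[OligoResidue, ...]
    mismatch_positions: frozenset[int] = frozenset()
    target_name: str | None = None
    target_start: int | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("design has no residues")
        bad = [p for p in self.mismatch_positions if not 0 <= p < len(self.residues)]
        if bad:
            raise ValueError(f"mismatch positions out of range: {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    @property
    def dna_runs(self) -> tuple[int, ...]:
        runs, run = [], 0
        for r in self.residues:
            if r.sugar is Sugar.DNA:
                run += 1
            elif run:
                runs.append(run)
                run = 0
        if run:
            runs.append(run)
        return tuple(runs)

    @property
    def category(self) -> str:
        """Inferred architecture: run pattern decides gapmer vs mixmer;
        declared mismatches promote to mismatch_mixmer."""
        if self.mismatch_positions:
            return "mismatch_mixmer"
        return "mixmer" if len(self.dna_runs) >= 2 else "gapmer"

    @property
    def footprint(self) -> tuple[int, int] | None:
        if self.target_start is None:
            return None
        return self.target_start, self.target_start + len(self)


def parse_oligo_notation(
    text: str,
    name: str = "",
    backbone: Backbone = Backbone.PS,
) -> OligoDesign:
    """Parse bracket/asterisk ASO notation into an :class:`OligoDesign`.

    Bracketed runs take the bracket's sugar chemistry; bases outside
    brackets must carry a ``∗``/``*`` suffix and become PS-DNA.  Whitespace
    is ignored.  Unbalanced or nested brackets, and bare bases with neither
    bracket context nor star, are rejected with the character offset.
    """
    residues: list[OligoResidue] = []
    sugar: Sugar | None = None
    expected_close: str | None = None
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in _BRACKETS:
            if expected_close is not None:
                raise ValueError(f"nested bracket {ch!r} at offset {i}")
            expected_close, sugar = _BRACKETS[ch]
            i += 1
            continue
        if ch in _CLOSERS:
            if expected_close != ch:
                raise ValueError(f"unbalanced bracket {ch!r} at offset {i}")
            expected_close, sugar = None, None
            i += 1
            continue
        base = ch.upper()
        if base not in "ACGTU":
            raise ValueError(f"unexpected character {ch!r} at offset {i}")
        if sugar is not None:
            residues.append(OligoResidue(base, sugar, backbone))
            i += 1
            continue
        # outside brackets: require a PS-DNA star suffix
        j = i + 1
        while j < n and text[j].isspace():
            j += 1
        if j < n and text[j] in ("*", PS_STAR):
            if base == "U":
                base = "T"
            residues.append(OligoResidue(base, Sugar.DNA, Backbone.PS))
            i = j + 1
            continue
        raise ValueError(
            f"base {ch!r} at offset {i} has neither bracket context nor '*'"
        )
    if expected_close is not None:
        raise ValueError(f"unclosed bracket, expected {expected_close!r}")
    if not residues:
        raise ValueError("empty design notation")
    return OligoDesign(name=name, residues=tuple(residues))


def serialize_oligo(design: OligoDesign) -> str:
    """Canonical notation: bracketed runs per sugar, ``∗`` after DNA bases,
    single spaces between runs.  ``parse(serialize(d))`` restores the
    residues exactly."""
    parts: list[str] = []
    i = 0
    res = design.residues
    while i < len(res):
        sugar = res[i].sugar
        j = i
        while j < len(res) and res[j].sugar is sugar:
            j += 1
        bases = "".join(r.base for r in res[i:j])
        if sugar is Sugar.DNA:
            parts.append(PS_STAR.join(bases) + PS_STAR)
        else:
            opener = {v[1]: k for k, v in _BRACKETS.items()}[sugar]
            closer = _BRACKETS[opener][0]
            parts.append(f"{opener}{bases}{closer}")
        i = j
    return " ".join(parts)


# ---------------------------------------------------------------------------
# sequence metrics
# ---------------------------------------------------------------------------

def gc_content(design: OligoDesign) -> float:
    """GC percentage, reported to one decimal."""
    seq = design.sequence
    return round(100.0 * sum(b in "GC" for b in seq) / len(seq), 1)


def dna_run_profile(
    design: OligoDesign, min_run: int = 4
) -> tuple[tuple[int, ...], bool]:
    """Maximal PS-DNA run lengths (5'→3') and the RNase H-competence flag.

    A duplex recruits RNase H only where an unmodified DNA stretch apposes
    the RNA; ``min_run`` sets the minimal competent run (default 4, the
    shortest gap observed to retain cleavage; 3 admits shorter-blocked
    mixmers).
    """
    runs = design.dna_runs
    return runs, bool(runs) and max(runs) >= min_run


@dataclass(frozen=True)
class TmConditions:
    """Hybridization conditions for the nearest-neighbor Tm model (mM / nM)."""

    na_mM: float = 50.0
    mg_mM: float = 0.0
    oligo_nM: float = 250.0
    target_nM: float = 0.0

    def __post_init__(self) -> None:
        if self.na_mM <= 0 or self.oligo_nM <= 0:
            raise ValueError("salt and oligo concentrations must be positive")


#: per-residue Tm increments for affinity-enhancing sugars (°C)
CHEMISTRY_TM_INCREMENT: dict[Sugar, float] = {
    Sugar.LNA: 3.0,
    Sugar.MOE2: 1.0,
    Sugar.OME2: 0.7,
    Sugar.DNA: 0.0,
}


def melting_temperature(
    design: OligoDesign,
    conditions: TmConditions | None = None,
    increments: Mapping[Sugar, float] = CHEMISTRY_TM_INCREMENT,
) -> float:
    """Model-based Tm (°C) of the ASO/RNA hybrid duplex.

    Nearest-neighbor DNA/RNA-hybrid thermodynamics on the base sequence,
    plus an additive per-residue increment for each affinity-enhancing sugar
    modification.  Designs shorter than 8 nt fall back to the empirical
    2+4 rule.  This is a transparent analogue for ranking and property
    checks, not a reproduction of any particular vendor tool.
    """
    conditions = conditions or TmConditions()
    seq_dna = design.sequence.replace("U", "T")
    if len(seq_dna) >= 8:
        tm = mt.Tm_NN(
            seq_dna,
            nn_table=mt.R_DNA_NN1,
            Na=conditions.na_mM,
            Mg=conditions.mg_mM,
            dnac1=conditions.oligo_nM,
            dnac2=conditions.target_nM,
        )
    else:
        tm = mt.Tm_Wallace(seq_dna)
    tm += sum(increments.get(r.sugar, 0.0) for r in design.residues)
    return float(tm)


# ---------------------------------------------------------------------------
# off-target scanning
# ---------------------------------------------------------------------------

_COMPLEMENT_DNA = str.maketrans("ACGT", "TGCA")


def reverse_complement_dna(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPLEMENT_DNA)[::-1]


@dataclass(frozen=True)
class OffTargetHit:
    transcript: str
    start: int
    mismatches: int


def off_target_scan(
    design: OligoDesign,
    transcripts: Mapping[str, str],
    max_mismatches: int = 0,
    intended: tuple[str, int, int] | None = None,
) -> list[OffTargetHit]:
    """Ungapped Hamming search for the design's target site elsewhere.

    Scans every transcript for the reverse complement of the ASO with up to
    ``max_mismatches`` substitutions (T/U equivalent, no gaps).  Hits
    overlapping ``intended`` — ``(transcript, start, end)`` of the intended
    binding site — are excluded.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    site = reverse_complement_dna(design.sequence)
    pattern = np.frombuffer(site.encode(), dtype=np.uint8)
    L = len(pattern)
    hits: list[OffTargetHit] = []
    for name, seq in transcripts.items():
        norm = seq.upper().replace("U", "T")
        if len(norm) < L:
            continue
        arr = np.frombuffer(norm.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mismatches = (windows != pattern).sum(axis=1)
        for start in np.nonzero(mismatches <= max_mismatches)[0]:
            start = int(start)
            if intended is not None:
                iname, istart, iend = intended
                if name == iname and start < iend and start + L > istart:
                    continue
            hits.append(OffTargetHit(name, start, int(mismatches[start])))
    return hits


@dataclass(frozen=True)
class DesignMetrics:
    """Per-design sequence metrics mirroring a design-table row."""

    name: str
    length: int
    gc_percent: float
    tm_celsius: float
    dna_runs: tuple[int, ...]
    longest_dna_run: int
    rnaseh_competent: bool
    category: str
    off_target_hits: int | None = None


def design_metrics(
    design: OligoDesign,
    transcripts: Mapping[str, str] | None = None,
    max_mismatches: int = 0,
    min_run: int = 4,
) -> DesignMetrics:
    runs, competent = dna_run_profile(design, min_run)
    hits = None
    if transcripts:
        intended = None
        if design.target_name is not None and design.target_start is not None:
            intended = (
                design.target_name,
                design.target_start,
                design.target_start + len(design),
            )
        hits = len(off_target_scan(design, transcripts, max_mismatches, intended))
    return DesignMetrics(
        name=design.name,
        length=len(design),
        gc_percent=gc_content(design),
        tm_celsius=round(melting_temperature(design), 1),
        dna_runs=runs,
        longest_dna_run=max(runs) if runs else 0,
        rnaseh_competent=competent,
        category=design.category,
        off_target_hits=hits,
    )
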