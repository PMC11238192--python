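"""Exon-structured transcripts and exon-skipped alleles.

A splice-site mutation that forces an internal, in-frame exon out of the
mature mRNA creates a *novel junction* between the flanking exons.  That
junction exists only on the mutant allele and is the natural anchor for an
allele-specific antisense oligonucleotide.  This module represents the
wild-type/mutant transcript pair, the coordinate map between the two
alleles, and the junction-centered sequence windows that downstream
structure prediction operates on.

Conventions
-----------
* Coordinates are 0-based, half-open.  Junctions are inter-residue offsets:
  junction ``j`` sits between positions ``j - 1`` and ``j``.
* The internal alphabet is RNA (``ACGU``); ``T`` is normalized to ``U`` on
  input.  FASTA serialization can restore the DNA alphabet via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

#: window lengths used for junction-centered structure prediction (nt)
DEFAULT_WINDOW_LENGTHS = (200, 500, 1000, 1500, 2000, 2500)


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert ``T`` to ``U``; reject non-nucleotide letters."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return seq


@dataclass(frozen=True)
class Exon:
    """A single exon with a normalized RNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"exon {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Window:
    """A contiguous, junction-centered view into a parent transcript.

    ``offset`` locates the window on the parent; ``junction_offset`` is the
    junction position inside the window (``floor(L/2)`` unless the window had
    to be truncated at a transcript end, in which case ``truncated`` is set).
    """

    allele: str
    sequence: str
    offset: int
    junction_offset: int
    requested_length: int
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.offset + len(self.sequence)


@dataclass(frozen=True)
class TranscriptPair:
    """Wild-type and exon-skipped transcript with their junction geometry.

    ``wt_junction`` is the boundary between the exon preceding the skip site
    and the skipped exon in the wild-type sequence; ``mut_junction`` is the
    novel junction in the mutant.  The two prefixes are identical and the
    suffixes are identical after shifting by ``skipped_length``.
    """

    wt_sequence: str
    mut_sequence: str
    wt_junction: int
    mut_junction: int
    skipped_length: int
    skipped_exon_id: str
    skipped_sequence: str
    in_frame: bool
    wt_exon_spans: tuple[tuple[str, int, int], ...] = field(default=())
    mut_exon_spans: tuple[tuple[str, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.wt_sequence) - len(self.mut_sequence) != self.skipped_length:
            raise ValueError("length difference does not equal skipped_length")
        j, k = self.wt_junction, self.mut_junction
        if self.wt_sequence[:j] != self.mut_sequence[:k]:
            raise ValueError("wild-type and mutant prefixes differ before the junction")
        if self.wt_sequence[j + self.skipped_length :] != self.mut_sequence[k:]:
            raise ValueError("wild-type and mutant suffixes differ after the junction")

    def map_to_wt(self, mut_pos: int) -> int:
        """Map a mutant-transcript position onto the wild-type transcript.

        Identity left of the junction, shifted by ``skipped_length`` right of
        it.  Total and strictly increasing over ``range(len(mut_sequence))``.
        """
        if not 0 <= mut_pos < len(self.mut_sequence):
            raise IndexError(f"mutant position {mut_pos} out of range")
        if mut_pos < self.mut_junction:
            return mut_pos
        return mut_pos + self.skipped_length

    def mut_exon_of(self, mut_pos: int) -> str:
        """Exon label containing a mutant-transcript position."""
        for label, start, end in self.mut_exon_spans:
            if start <= mut_pos < end:
                return label
        raise IndexError(f"mutant position {mut_pos} outside all exon spans")

    def mut_exon_span(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.mut_exon_spans:
            if lab == label:
                return start, end
        raise KeyError(f"no exon {label!r} on the mutant transcript")

    def reconstruct_wt(self) -> str:
        """Re-insert the skipped exon at the junction (round-trip check)."""
        k = self.mut_junction
        return self.mut_sequence[:k] + self.skipped_sequence + self.mut_sequence[k:]


def build_junction_pair(exons: Sequence[Exon], skip_index: int) -> TranscriptPair:
    """Concatenate exons into the wild-type transcript and drop one internal
    exon to form the exon-skipped mutant allele.

    The skipped exon must be internal: skipping a terminal exon creates no
    novel exon-exon junction.  The ``in_frame`` flag is set when the skipped
    exon length is a multiple of 3.
    """
    if not exons:
        raise ValueError("exon list is empty")
    if not 0 < skip_index < len(exons) - 1:
        raise ValueError(
            f"skip_index {skip_index} must name an internal exon "
            f"(1..{len(exons) - 2})"
        )
    wt_parts: list[tuple[str, int, int]] = []
    pos = 0
    for ex in exons:
        wt_parts.append((ex.id, pos, pos + len(ex)))
        pos += len(ex)
    wt_seq = "".join(ex.sequence for ex in exons)

    skipped = exons[skip_index]
    mut_exons = [ex for i, ex in enumerate(exons) if i != skip_index]
    mut_parts = []
    pos = 0
    for ex in mut_exons:
        mut_parts.append((ex.id, pos, pos + len(ex)))
        pos += len(ex)
    mut_seq = "".join(ex.sequence for ex in mut_exons)

    junction = wt_parts[skip_index][1]  # start of the skipped exon in wt
    return TranscriptPair(
        wt_sequence=wt_seq,
        mut_sequence=mut_seq,
        wt_junction=junction,
        mut_junction=junction,
        skipped_length=len(skipped),
        skipped_exon_id=skipped.id,
        skipped_sequence=skipped.sequence,
        in_frame=len(skipped) % 3 == 0,
        wt_exon_spans=tuple(wt_parts),
        mut_exon_spans=tuple(mut_parts),
    )


def _centered_window(
    allele: str, sequence: str, junction: int, length: int
) -> Window:
    if length < 2:
        raise ValueError(f"window length must be >= 2, got {length}")
    start = junction - length // 2
    end = start + length
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if end > len(sequence):
        end, truncated = len(sequence), True
    if truncated:
        warnings.warn(
            f"{allele} window of {length} nt truncated to "
            f"[{start}, {end}) near a transcript end",
            stacklevel=3,
        )
    return Window(
        allele=allele,
        sequence=sequence[start:end],
        offset=start,
        junction_offset=junction - start,
        requested_length=length,
        truncated=truncated,
    )


def extract_centered_windows(
    pair: TranscriptPair,
    lengths: Iterable[int] = DEFAULT_WINDOW_LENGTHS,
) -> dict[int, dict[str, Window]]:
    """Junction-centered windows per allele, one per requested length.

    The wild-type window is centered on the boundary between the upstream
    exon and the skipped exon; the mutant window on the novel junction.  For
    even/odd lengths alike the junction lands at offset ``floor(L/2)``.
    Windows that would overrun a transcript end are truncated (with a
    warning and the ``truncated`` flag) rather than rejected.
    """
    out: dict[int, dict[str, Window]] = {}
    for length in sorted(set(lengths)):
        out[length] = {
            "wt": _centered_window("wt", pair.wt_sequence, pair.wt_junction, length),
            "mut": _centered_window(
                "mut", pair.mut_sequence, pair.mut_junction, length
            ),
        }
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: normalized RNA sequence}``."""
    return {
        rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(
    sequences: dict[str, str], path: str | Path, *, as_dna: bool = False
) -> None:
    """Write sequences as FASTA; ``as_dna`` restores the T alphabet."""
    records = []
    for name, seq in sequences.items():
        out = seq.replace("U", "T") if as_dna else seq
        records.append(SeqRecord(Seq(out), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_exon_table(path: str | Path) -> list[Exon]:
    """Read a two-column TSV (id, sequence) into an ordered exon list."""
    exons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "id" and lineno == 1:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>sequence'")
            exons.append(Exon(fields[0], fields[1]))
    if not exons:
        raise ValueError(f"{path}: no exons found")
    return exons
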