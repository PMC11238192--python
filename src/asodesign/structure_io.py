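"""Readers/writers for externally predicted structures (CT, dot-bracket).

The CT ("connect") dialect follows mfold / UNAFold output: a header line
whose first token is the sequence length (typically followed by an energy
annotation such as ``dG = -12.3``), then one line per nucleotide with six
columns: index, base, previous index, next index, partner index (0 when
unpaired) and the index again.  All indices are 1-based.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from .structure import SecondaryStructure, StructureEnsemble
from .transcripts import normalize_rna


def parse_dotbracket(struct: str) -> tuple[int, ...]:
    """Pairing table from a dot-bracket string (no pseudoknot layers)."""
    pairing = [-1] * len(struct)
    stack: list[int] = []
    for i, ch in enumerate(struct):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairing[j], pairing[i] = i, j
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return tuple(pairing)


def to_dotbracket(structure: SecondaryStructure) -> str:
    out = []
    for i, j in enumerate(structure.pairing):
        out.append("." if j < 0 else "(" if j > i else ")")
    return "".join(out)


_CT_ENERGY_RE = re.compile(r"d?G\s*=\s*(-?\d+\.?\d*)", re.IGNORECASE)


def parse_ct(text: str) -> list[tuple[str, tuple[int, ...], float]]:
    """Parse one or more concatenated CT records from a string.

    Returns ``(sequence, pairing, energy)`` per record; malformed or
    self-inconsistent partner columns raise with the offending line number.
    """
    lines = text.splitlines()
    records = []
    lineno = 0
    while lineno < len(lines):
        line = lines[lineno].strip()
        if not line:
            lineno += 1
            continue
        header_line = lineno + 1
        tokens = line.split()
        try:
            n = int(tokens[0])
        except ValueError as exc:
            raise ValueError(
                f"CT line {header_line}: header must start with the length"
            ) from exc
        m = _CT_ENERGY_RE.search(line)
        energy = float(m.group(1)) if m else 0.0
        bases: list[str] = []
        pairing = [-1] * n
        for k in range(n):
            lineno += 1
            if lineno >= len(lines):
                raise ValueError(f"CT record at line {header_line}: truncated")
            fields = lines[lineno].split()
            if len(fields) < 6:
                raise ValueError(f"CT line {lineno + 1}: expected 6 columns")
            try:
                idx, partner = int(fields[0]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"CT line {lineno + 1}: non-integer index") from exc
            if idx != k + 1:
                raise ValueError(
                    f"CT line {lineno + 1}: index {idx}, expected {k + 1}"
                )
            bases.append(fields[1])
            pairing[k] = partner - 1 if partner > 0 else -1
        for i, j in enumerate(pairing):
            if j >= 0 and (j >= n or pairing[j] != i):
                raise ValueError(
                    f"CT record at line {header_line}: partner column "
                    f"inconsistent at position {i + 1}"
                )
        records.append((normalize_rna("".join(bases)), tuple(pairing), energy))
        lineno += 1
    if not records:
        raise ValueError("no CT records found")
    return records


def write_ct(
    sequence: str, structure: SecondaryStructure, path: str | Path, name: str = "seq"
) -> None:
    n = len(sequence)
    with open(path, "w") as fh:
        fh.write(f"{n} dG = {structure.energy:.2f} {name}\n")
        for i in range(n):
            partner = structure.pairing[i] + 1 if structure.pairing[i] >= 0 else 0
            fh.write(
                f"{i + 1} {sequence[i]} {i} {i + 2 if i + 1 < n else 0} "
                f"{partner} {i + 1}\n"
            )


def _read_dotbracket_file(text: str) -> tuple[str | None, list[tuple[int, ...]]]:
    """Dot-bracket file: optional '>' headers and sequence lines, plus one or
    more structure lines made of ``.()`` characters."""
    seq_parts: list[str] = []
    structures: list[tuple[int, ...]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(">") or line.startswith("#"):
            continue
        if set(line) <= set(".()"):
            structures.append(parse_dotbracket(line))
        else:
            seq_parts.append(line)
    seq = normalize_rna("".join(seq_parts)) if seq_parts else None
    return seq, structures


def _check_sequence(found: str | None, expected: str, source: str) -> None:
    if found is None:
        return
    if len(found) != len(expected):
        raise ValueError(
            f"{source}: sequence length {len(found)} != expected {len(expected)}"
        )
    for i, (a, b) in enumerate(zip(found, expected)):
        if a != b:
            raise ValueError(
                f"{source}: sequence differs from the target at position {i} "
                f"({a!r} != {b!r})"
            )


def import_ensemble(
    files: Iterable[str | Path], sequence: str
) -> StructureEnsemble:
    """Build an ensemble from CT and/or dot-bracket files.

    Every file must describe the given sequence (case- and T/U-insensitive);
    the first differing position is reported otherwise.  Each CT record or
    dot-bracket structure line becomes one ensemble member.
    """
    seq = normalize_rna(sequence)
    structures: list[SecondaryStructure] = []
    for path in files:
        path = Path(path)
        text = path.read_text()
        stripped = text.lstrip()
        first_token = stripped.split(None, 1)[0] if stripped else ""
        if first_token.isdigit():
            for rec_seq, pairing, energy in parse_ct(text):
                _check_sequence(rec_seq, seq, str(path))
                s = SecondaryStructure(pairing, energy)
                s.validate(seq)
                structures.append(s)
        else:
            file_seq, pairings = _read_dotbracket_file(text)
            _check_sequence(file_seq, seq, str(path))
            for pairing in pairings:
                if len(pairing) != len(seq):
                    raise ValueError(
                        f"{path}: structure length {len(pairing)} != "
                        f"sequence length {len(seq)}"
                    )
                s = SecondaryStructure(pairing, 0.0)
                s.validate(seq)
                structures.append(s)
    if not structures:
        raise ValueError("no structures imported")
    return StructureEnsemble(seq, tuple(structures), source="imported")
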