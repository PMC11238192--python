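"""RNA secondary-structure ensembles and ss-count accessibility.

The design strategy implemented by this package does not need full
thermodynamic folding — it needs a *per-nucleotide accessibility signal*
that can be compared between the mutant and wild-type alleles.  The signal
is the ss-count: over an ensemble of predicted structures, the number of
structures in which a nucleotide is single-stranded.  A position unpaired
in all structures of a 30-structure ensemble has ss-count 30 (fully open);
a position paired in all of them has ss-count 0 (fully closed).

The built-in folding engine uses a deliberately simple nested-structure
energy model (per-pair scores, configurable), with two regimes:

* **exhaustive** — for short sequences, every valid structure within an
  energy band of the optimum is enumerated (unique-decomposition
  backtracking with lower-bound pruning);
* **sampled** — for longer sequences, a seeded Boltzmann-weighted sample of
  structures is drawn from the exact partition function of the same model;
  the optimum structure is always part of the ensemble.

Externally computed ensembles (CT or dot-bracket files, e.g. from mfold /
UNAFold) can be imported instead; the ss-count machinery is agnostic to the
ensemble's origin.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transcripts import TranscriptPair, normalize_rna

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

#: default per-pair stacking-free scores, model units (negative = stabilizing)
DEFAULT_PAIR_SCORES: dict[str, float] = {"GC": -3.0, "AU": -2.0, "GU": -1.0}


@dataclass(frozen=True)
class FoldConfig:
    """Parameters of the baseline folding engine.

    The energy of a structure is the sum of its pair scores plus
    ``stack_bonus`` for every stacked pair — a pair (i, j) whose inner
    neighbor (i+1, j-1) is also paired.  The stacking term makes contiguous
    helices cooperative, as in real RNA thermodynamics: without it, many
    scattered isolated pairs are entropically indistinguishable from one
    specific helix and no sequence region ever folds decisively closed.

    ``pair_scores`` maps the unordered pair kind (``GC``/``AU``/``GU``) to a
    score; ``min_loop`` is the minimum number of unpaired nucleotides in a
    hairpin loop; sequences no longer than ``exhaustive_cutoff`` are folded
    exhaustively within ``energy_band`` of the optimum, longer ones are
    sampled (``n_samples`` structures at temperature ``kT``, seeded).
    """

    pair_scores: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_SCORES)
    )
    stack_bonus: float = -2.0
    min_loop: int = 3
    exhaustive_cutoff: int = 25
    energy_band: float = 2.0
    n_samples: int = 30
    kT: float = 1.0
    seed: int = 0

    def pair_energy(self, a: str, b: str) -> float | None:
        """Score of pairing bases ``a``/``b``; ``None`` if not pairable."""
        if a + b not in CANONICAL_PAIRS:
            return None
        kind = a + b if a + b in self.pair_scores else b + a
        return float(self.pair_scores[kind])


@dataclass(frozen=True)
class SecondaryStructure:
    """One nested secondary structure: per-position partner (-1 = unpaired)."""

    pairing: tuple[int, ...]
    energy: float

    def __len__(self) -> int:
        return len(self.pairing)

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (i, j) for i, j in enumerate(self.pairing) if j > i
        )

    def unpaired_mask(self) -> np.ndarray:
        return np.asarray(self.pairing) < 0

    def validate(self, sequence: str, min_loop: int = 3) -> None:
        """Check involution, nestedness, loop size and pair legality."""
        n = len(sequence)
        if len(self.pairing) != n:
            raise ValueError("pairing length does not match sequence")
        for i, j in enumerate(self.pairing):
            if j < 0:
                continue
            if not 0 <= j < n or j == i:
                raise ValueError(f"invalid partner {j} at position {i}")
            if self.pairing[j] != i:
                raise ValueError(f"pairing not an involution at {i}<->{j}")
            if j > i:
                if j - i - 1 < min_loop:
                    raise ValueError(f"hairpin loop < {min_loop} at pair ({i},{j})")
                if sequence[i] + sequence[j] not in CANONICAL_PAIRS:
                    raise ValueError(
                        f"non-canonical pair {sequence[i]}{sequence[j]} at ({i},{j})"
                    )
        # nestedness: no crossing pairs
        open_stack: list[int] = []
        for i, j in enumerate(self.pairing):
            if j > i:
                open_stack.append(j)
            elif 0 <= j < i:
                if not open_stack or open_stack[-1] != i:
                    raise ValueError(f"crossing (pseudoknotted) pair at ({j},{i})")
                open_stack.pop()


@dataclass(frozen=True)
class StructureEnsemble:
    """A sequence together with one or more predicted structures."""

    sequence: str
    structures: tuple[SecondaryStructure, ...]
    source: str = "computed"  # or "imported"

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("ensemble must contain at least one structure")

    @property
    def n_structures(self) -> int:
        return len(self.structures)


@dataclass(frozen=True)
class SSCountProfile:
    """Per-position single-strandedness counts over an ensemble.

    ``offset`` locates position 0 of the profile on a parent transcript when
    the profile was computed on a window.
    """

    ss_count: tuple[int, ...]
    n_structures: int
    offset: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= c <= self.n_structures for c in self.ss_count):
            raise ValueError("ss_count outside [0, n_structures]")

    def __len__(self) -> int:
        return len(self.ss_count)

    @property
    def ss_fraction(self) -> np.ndarray:
        return np.asarray(self.ss_count, dtype=float) / self.n_structures

    @property
    def end(self) -> int:
        return self.offset + len(self.ss_count)


class AccessClass(str, Enum):
    OPEN = "open"
    SEMI_OPEN = "semi_open"
    CLOSED = "closed"


@dataclass(frozen=True)
class AccessibilityMap:
    """Three-class accessibility per position, plus the underlying fractions."""

    classes: tuple[AccessClass, ...]
    ss_fraction: tuple[float, ...]
    t_open: float
    t_closed: float
    offset: int = 0

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def end(self) -> int:
        return self.offset + len(self.classes)

    def class_at(self, transcript_pos: int) -> AccessClass:
        return self.classes[transcript_pos - self.offset]

    def fraction_at(self, transcript_pos: int) -> float:
        return self.ss_fraction[transcript_pos - self.offset]


@dataclass(frozen=True)
class DifferentialMap:
    """Mutant-coordinate positions that drive allele-selective design.

    ``mut_accessible_wt_closed`` — open or semi-open on the mutant allele but
    closed on the wild-type allele: where RNA-modified nucleotides buy the
    most mutant-specific affinity.  ``open_in_both`` — open on both alleles:
    candidate sites for discriminating mismatches.  ``margin`` records the
    mutant-minus-wild-type ss-fraction at every compared position.
    """

    mut_accessible_wt_closed: frozenset[int]
    open_in_both: frozenset[int]
    margin: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mut_accessible_wt_closed & self.open_in_both:
            raise ValueError("differential sets must be disjoint")


# ---------------------------------------------------------------------------
# folding engine
# ---------------------------------------------------------------------------

def _pair_matrix(seq: str, config: FoldConfig) -> np.ndarray:
    """Energy of pairing (i, j); +inf where not pairable or loop too short."""
    n = len(seq)
    em = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + config.min_loop + 1, n):
            e = config.pair_energy(seq[i], seq[j])
            if e is not None:
                em[i, j] = e
    return em


def _emin_tables(
    em: np.ndarray, config: FoldConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum energy per interval [i, j].

    ``E[i, j]`` — over all nested structures; ``Eb[i, j]`` — over structures
    in which i pairs j (inf where unpairable).  The stacked continuation of
    a helix takes the ``stack_bonus`` discount.
    """
    n = em.shape[0]
    sigma = config.stack_bonus
    E = np.zeros((n + 2, n + 2))
    Eb = np.full((n + 2, n + 2), np.inf)
    for d in range(config.min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            if np.isfinite(em[i, j]):
                interior = min(E[i + 1, j - 1], Eb[i + 1, j - 1] + sigma)
                Eb[i, j] = em[i, j] + interior
            best = E[i + 1, j]
            ks = np.arange(i + config.min_loop + 1, j + 1)
            cand = Eb[i, ks] + E[ks + 1, j]
            kbest = cand.min()
            if kbest < best:
                best = kbest
            E[i, j] = best
    return E, Eb


def _mfe_traceback(
    seq: str, em: np.ndarray, E: np.ndarray, Eb: np.ndarray, config: FoldConfig
) -> tuple[int, ...]:
    n = len(seq)
    sigma = config.stack_bonus
    pairing = [-1] * n
    stack: list[tuple[str, int, int]] = [("z", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if i >= j:
            continue
        if state == "b":
            pairing[i], pairing[j] = j, i
            if Eb[i + 1, j - 1] + sigma <= E[i + 1, j - 1] + 1e-9:
                stack.append(("b", i + 1, j - 1))
            else:
                stack.append(("z", i + 1, j - 1))
            continue
        if E[i + 1, j] <= E[i, j] + 1e-9 and np.isclose(E[i, j], E[i + 1, j]):
            stack.append(("z", i + 1, j))
            continue
        found = False
        for k in range(i + config.min_loop + 1, j + 1):
            if np.isclose(E[i, j], Eb[i, k] + E[k + 1, j]):
                stack.append(("b", i, k))
                stack.append(("z", k + 1, j))
                found = True
                break
        if not found:  # numerical fallback: leave i unpaired
            stack.append(("z", i + 1, j))
    return tuple(pairing)


def _enumerate_band(
    seq: str,
    em: np.ndarray,
    E: np.ndarray,
    Eb: np.ndarray,
    budget: float,
    config: FoldConfig,
) -> list[tuple[frozenset[tuple[int, int]], float]]:
    """All structures on [0, n-1] with energy <= budget.

    Unique decomposition (i unpaired, or i pairs some k) with lower-bound
    pruning from the E/Eb tables; the stacking discount is applied when the
    enclosed interval's leading pair continues the helix.
    """
    sys.setrecursionlimit(10000)
    sigma = config.stack_bonus
    cache: dict[tuple[str, int, int, float], list] = {}

    def enum_z(i: int, j: int, budget: float):
        if i >= j:
            return [(frozenset(), 0.0)] if budget >= -1e-9 else []
        key = ("z", i, j, round(budget, 6))
        if key in cache:
            return cache[key]
        out = []
        if E[i + 1, j] <= budget + 1e-9:
            out.extend(enum_z(i + 1, j, budget))
        for k in range(i + config.min_loop + 1, j + 1):
            if Eb[i, k] + E[k + 1, j] > budget + 1e-9:
                continue
            for left, el in enum_b(i, k, budget - E[k + 1, j]):
                for right, er in enum_z(k + 1, j, budget - el):
                    if el + er <= budget + 1e-9:
                        out.append((left | right, el + er))
        cache[key] = out
        return out

    def enum_b(i: int, j: int, budget: float):
        """Structures on [i, j] where i pairs j, with their energies."""
        key = ("b", i, j, round(budget, 6))
        if key in cache:
            return cache[key]
        e = em[i, j]
        out = []
        if np.isfinite(e) and Eb[i, j] <= budget + 1e-9:
            for interior, ei in enum_z(i + 1, j - 1, budget - e - min(sigma, 0.0)):
                stacked = (i + 1, j - 1) in interior
                total = e + ei + (sigma if stacked else 0.0)
                if total <= budget + 1e-9:
                    out.append((interior | {(i, j)}, total))
        cache[key] = out
        return out

    n = len(seq)
    return [(p, e) for p, e in enum_z(0, n - 1, budget) if e <= budget + 1e-9]


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    if np.isneginf(m):
        return -np.inf
    return float(m + np.log(np.exp(v - m).sum()))


def _logz_tables(
    em: np.ndarray, config: FoldConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Log partition function per interval.

    ``LZ`` — all structures; ``LZb`` — structures where the interval ends
    pair each other.  The stacked continuation carries the Boltzmann boost
    ``s = exp(-stack_bonus/kT)``; its decomposition adds ``(s - 1) * Zb`` on
    top of the plain interior (which already counts the stacked pair once).
    """
    n = em.shape[0]
    with np.errstate(invalid="ignore"):
        w = -em / config.kT  # -inf where unpairable
    log_s_minus_1 = (
        np.log(np.expm1(-config.stack_bonus / config.kT))
        if config.stack_bonus < 0
        else -np.inf
    )
    LZ = np.zeros((n + 2, n + 2))
    LZb = np.full((n + 2, n + 2), -np.inf)
    for d in range(config.min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            if np.isfinite(w[i, j]):
                interior = np.logaddexp(
                    LZ[i + 1, j - 1], log_s_minus_1 + LZb[i + 1, j - 1]
                )
                LZb[i, j] = w[i, j] + interior
            ks = np.arange(i + config.min_loop + 1, j + 1)
            vals = LZb[i, ks] + LZ[ks + 1, j]
            LZ[i, j] = np.logaddexp(LZ[i + 1, j], _logsumexp(vals))
    return LZ, LZb


def _sample_structure(
    em: np.ndarray,
    LZ: np.ndarray,
    LZb: np.ndarray,
    config: FoldConfig,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    n = em.shape[0]
    log_s_minus_1 = (
        np.log(np.expm1(-config.stack_bonus / config.kT))
        if config.stack_bonus < 0
        else -np.inf
    )
    pairing = [-1] * n
    stack: list[tuple[str, int, int]] = [("z", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if i >= j:
            continue
        if state == "b":
            pairing[i], pairing[j] = j, i
            boosted = log_s_minus_1 + LZb[i + 1, j - 1]
            total = np.logaddexp(LZ[i + 1, j - 1], boosted)
            if np.log(rng.random() + 1e-300) < boosted - total:
                stack.append(("b", i + 1, j - 1))
            else:
                stack.append(("z", i + 1, j - 1))
            continue
        # P(i unpaired) = Z(i+1, j) / Z(i, j)
        if np.log(rng.random() + 1e-300) < LZ[i + 1, j] - LZ[i, j]:
            stack.append(("z", i + 1, j))
            continue
        ks = np.arange(i + config.min_loop + 1, j + 1)
        vals = LZb[i, ks] + LZ[ks + 1, j]
        finite = np.isfinite(vals)
        if not finite.any():
            stack.append(("z", i + 1, j))
            continue
        probs = np.exp(vals[finite] - _logsumexp(vals[finite]))
        k = int(rng.choice(ks[finite], p=probs / probs.sum()))
        stack.append(("b", i, k))
        stack.append(("z", k + 1, j))
    return tuple(pairing)


def structure_energy(
    pairing: Sequence[int], seq: str, config: FoldConfig
) -> float:
    """Energy of an explicit structure: pair scores plus stacking bonuses."""
    total = 0.0
    for i, j in enumerate(pairing):
        if j > i:
            e = config.pair_energy(seq[i], seq[j])
            if e is None:
                raise ValueError(f"illegal pair at ({i},{j})")
            total += e
            if j - i >= 2 and pairing[i + 1] == j - 1:
                total += config.stack_bonus
    return total


def fold_ensemble(sequence: str, config: FoldConfig | None = None) -> StructureEnsemble:
    """Predict a structure ensemble for one sequence.

    Short sequences (``<= config.exhaustive_cutoff``) yield *all* valid
    structures within ``config.energy_band`` of the optimum, deterministically
    ordered by (energy, pairing).  Longer sequences yield a seeded Boltzmann
    sample of ``config.n_samples`` structures that always contains the
    optimum structure.
    """
    config = config or FoldConfig()
    seq = normalize_rna(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    em = _pair_matrix(seq, config)
    E, Eb = _emin_tables(em, config)
    emin = E[0, n - 1] if n > 1 else 0.0

    if n <= config.exhaustive_cutoff:
        found = _enumerate_band(seq, em, E, Eb, emin + config.energy_band, config)
        structures = sorted(
            (
                SecondaryStructure(_pairs_to_pairing(p, n), e)
                for p, e in found
            ),
            key=lambda s: (s.energy, s.pairing),
        )
        return StructureEnsemble(seq, tuple(structures), source="computed")

    LZ, LZb = _logz_tables(em, config)
    rng = np.random.default_rng(config.seed)
    mfe_pairing = _mfe_traceback(seq, em, E, Eb, config)
    samples = [
        _sample_structure(em, LZ, LZb, config, rng)
        for _ in range(config.n_samples)
    ]
    if mfe_pairing not in samples:
        samples[-1] = mfe_pairing
    structures = tuple(
        SecondaryStructure(p, structure_energy(p, seq, config)) for p in samples
    )
    return StructureEnsemble(seq, structures, source="computed")


def _pairs_to_pairing(pairs: Iterable[tuple[int, int]], n: int) -> tuple[int, ...]:
    pairing = [-1] * n
    for i, j in pairs:
        pairing[i], pairing[j] = j, i
    return tuple(pairing)


# ---------------------------------------------------------------------------
# ss-count and classification
# ---------------------------------------------------------------------------

def compute_ss_count(ensemble: StructureEnsemble, offset: int = 0) -> SSCountProfile:
    """Tally, per position, the structures in which it is single-stranded."""
    masks = np.stack([s.unpaired_mask() for s in ensemble.structures])
    counts = masks.sum(axis=0)
    return SSCountProfile(
        ss_count=tuple(int(c) for c in counts),
        n_structures=ensemble.n_structures,
        offset=offset,
    )


#: symmetric-tertile defaults for the open / semi-open / closed partition
DEFAULT_THRESHOLDS = (2.0 / 3.0, 1.0 / 3.0)


def classify_accessibility(
    profile: SSCountProfile,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> AccessibilityMap:
    """Partition positions into open / semi-open / closed by ss-fraction.

    ``thresholds = (t_open, t_closed)``: open iff fraction >= t_open, closed
    iff fraction <= t_closed, semi-open otherwise.
    """
    t_open, t_closed = thresholds
    if not (0.0 <= t_closed < t_open <= 1.0):
        raise ValueError(
            f"need 0 <= t_closed < t_open <= 1, got ({t_open}, {t_closed})"
        )
    frac = profile.ss_fraction
    classes = tuple(
        AccessClass.OPEN
        if f >= t_open
        else AccessClass.CLOSED
        if f <= t_closed
        else AccessClass.SEMI_OPEN
        for f in frac
    )
    return AccessibilityMap(
        classes=classes,
        ss_fraction=tuple(float(f) for f in frac),
        t_open=t_open,
        t_closed=t_closed,
        offset=profile.offset,
    )


def differential_accessibility(
    mut_map: AccessibilityMap,
    wt_map: AccessibilityMap,
    pair: TranscriptPair,
    region: str | None = None,
) -> DifferentialMap:
    """Compare allele accessibility through the exon coordinate map.

    Iterates mutant positions covered by ``mut_map``, maps each onto the
    wild-type transcript and compares classes where ``wt_map`` also covers
    the image.  ``region`` (an exon label) restricts the mismatch-candidate
    ``open_in_both`` set to that exon.
    """
    sel: set[int] = set()
    both: set[int] = set()
    margin: dict[int, float] = {}
    region_span = pair.mut_exon_span(region) if region is not None else None
    compared = 0
    for mpos in range(mut_map.offset, mut_map.end):
        wpos = pair.map_to_wt(mpos) if mpos < len(pair.mut_sequence) else None
        if wpos is None or not wt_map.offset <= wpos < wt_map.end:
            continue
        compared += 1
        mcls = mut_map.class_at(mpos)
        wcls = wt_map.class_at(wpos)
        margin[mpos] = mut_map.fraction_at(mpos) - wt_map.fraction_at(wpos)
        if mcls in (AccessClass.OPEN, AccessClass.SEMI_OPEN) and (
            wcls is AccessClass.CLOSED
        ):
            sel.add(mpos)
        elif mcls is AccessClass.OPEN and wcls is AccessClass.OPEN:
            if region_span is None or region_span[0] <= mpos < region_span[1]:
                both.add(mpos)
    if compared == 0:
        raise ValueError("accessibility maps do not overlap after coordinate mapping")
    return DifferentialMap(
        mut_accessible_wt_closed=frozenset(sel),
        open_in_both=frozenset(both),
        margin=margin,
    )


def consensus_class(classes: Sequence[AccessClass]) -> AccessClass:
    """Majority class across window lengths; ties resolve to semi-open."""
    counts = {c: 0 for c in AccessClass}
    for c in classes:
        counts[c] += 1
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else AccessClass.SEMI_OPEN


def export_heatmap_table(
    sequence: str,
    profiles: Mapping[int, SSCountProfile],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    path: str | None = None,
) -> pd.DataFrame:
    """Tabular equivalent of the red/green accessibility heatmap.

    One row per transcript position covered by at least one window profile;
    per-window ss-count and class columns plus a majority-vote consensus
    class (ties break to semi-open).
    """
    seq = normalize_rna(sequence)
    maps = {L: classify_accessibility(p, thresholds) for L, p in profiles.items()}
    positions = sorted(
        {pos for p in profiles.values() for pos in range(p.offset, p.end)}
    )
    rows = []
    for pos in positions:
        row: dict[str, object] = {"position": pos, "base": seq[pos]}
        votes = []
        for L in sorted(profiles):
            prof, amap = profiles[L], maps[L]
            if prof.offset <= pos < prof.end:
                row[f"ss_count_{L}"] = prof.ss_count[pos - prof.offset]
                cls = amap.class_at(pos)
                row[f"class_{L}"] = cls.value
                votes.append(cls)
            else:
                row[f"ss_count_{L}"] = pd.NA
                row[f"class_{L}"] = pd.NA
        row["consensus"] = consensus_class(votes).value
        rows.append(row)
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
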