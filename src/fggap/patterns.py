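"""Sequence-level detection of integrin-blade motifs.

Two motifs anchor each ~60-residue blade of the integrin-type 7-bladed
beta-propeller domain:

* the **Cage** (FG-GAP) consensus repeat ``phi-phi-G-phi X13-20 P X2-15 G
  X5-8`` (phi = aromatic residue, X = any residue), whose fixed letters sit
  in loop segments A, B and C of a blade, and
* the **DxDxDG-like calcium-binding loop**, a six-residue loop whose
  alternating acidic side chains coordinate a Ca2+ ion at the opposite end
  of the blade.

The scanners here enumerate *every* anchor placement satisfying a pattern
(overlaps permitted); greedy or leftmost-only matching would destroy valid
seven-blade chains downstream.  Coordinates are 1-based, closed intervals
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: letters tolerated in input sequences but never matching a fixed anchor
AMBIGUOUS_AA = set("BZXUO")
ALLOWED_INPUT = STANDARD_AA | AMBIGUOUS_AA


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a letter outside the amino-acid alphabet."""

    def __init__(self, letter: str, position: int):
        self.letter = letter
        self.position = position
        super().__init__(
            f"illegal residue letter {letter!r} at position {position} (1-based)"
        )


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    for i, letter in enumerate(seq):
        if letter not in ALLOWED_INPUT:
            raise SequenceAlphabetError(letter, i + 1)
    return seq


@dataclass(frozen=True)
class CagePatternSpec:
    """Parameterization of the Cage consensus ``phi phi G phi X{g1} P X{g2} G X{tail}``.

    Parameters
    ----------
    aromatic_set :
        Letters accepted at the four ``phi`` (aromatic) anchor positions.
        Histidine is excluded by default but may be added.
    gap1_range :
        Inclusive bounds on the spacer between the ``phi phi G phi`` block
        and the proline anchor (default 13..20).
    gap2_range :
        Inclusive bounds on the spacer between the proline and the final
        glycine anchor (default 2..15).
    tail_range :
        Inclusive bounds on the trailing stretch after the final glycine
        (default 5..8); a match requires at least the lower bound of tail
        residues and extends over at most the upper bound.
    """

    aromatic_set: frozenset = frozenset("FWY")
    gap1_range: tuple[int, int] = (13, 20)
    gap2_range: tuple[int, int] = (2, 15)
    tail_range: tuple[int, int] = (5, 8)

    def __post_init__(self):
        for lo, hi in (self.gap1_range, self.gap2_range, self.tail_range):
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid gap interval [{lo}, {hi}]")
        if not self.aromatic_set:
            raise ValueError("aromatic_set must be non-empty")
        if not set(self.aromatic_set) <= STANDARD_AA:
            raise ValueError("aromatic_set must be standard residue letters")
        object.__setattr__(self, "aromatic_set", frozenset(self.aromatic_set))

    @property
    def min_length(self) -> int:
        return 4 + self.gap1_range[0] + 1 + self.gap2_range[0] + 1 + self.tail_range[0]

    @property
    def max_length(self) -> int:
        return 4 + self.gap1_range[1] + 1 + self.gap2_range[1] + 1 + self.tail_range[1]


@dataclass(frozen=True)
class CaMotifSpec:
    """Parameterization of the six-residue DxDxDG calcium-binding loop.

    Positions 1, 3 and 5 must come from ``coordinating_alphabet`` (default
    ``{D, N}``: asparagine substitutions are common in this loop family; use
    ``frozenset("D")`` for a strict-aspartate mode) and position 6 must be
    glycine.
    """

    coordinating_alphabet: frozenset = frozenset("DN")
    length: int = 6

    def __post_init__(self):
        if self.length != 6:
            raise ValueError("the Ca-binding loop pattern is fixed at 6 residues")
        allowed = set("DNEQST")
        if not set(self.coordinating_alphabet) <= allowed:
            raise ValueError(
                f"coordinating_alphabet must be a subset of {sorted(allowed)}"
            )
        if not self.coordinating_alphabet:
            raise ValueError("coordinating_alphabet must be non-empty")
        object.__setattr__(
            self, "coordinating_alphabet", frozenset(self.coordinating_alphabet)
        )


@dataclass(frozen=True)
class MotifMatch:
    """A located occurrence of a motif, 1-based closed coordinates.

    ``anchors`` holds the positions of the fixed letters, in order:
    (phi, phi, G, phi, P, G) for a Cage match, (D, D, D, G) for a Ca match.
    """

    sequence_id: str
    start: int
    end: int
    anchors: tuple[int, ...]
    kind: str  # "cage" | "ca"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if any(b <= a for a, b in zip(self.anchors, self.anchors[1:])):
            raise ValueError("anchors must be strictly increasing")
        if self.anchors and not (
            self.start <= self.anchors[0] and self.anchors[-1] <= self.end
        ):
            raise ValueError("anchors must lie within [start, end]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def shifted(self, offset: int) -> "MotifMatch":
        return replace(
            self,
            start=self.start + offset,
            end=self.end + offset,
            anchors=tuple(a + offset for a in self.anchors),
        )


def scan_cage(
    sequence: str,
    spec: CagePatternSpec | None = None,
    sequence_id: str = "",
) -> list[MotifMatch]:
    """Find every distinct anchor placement of the Cage consensus.

    All gap combinations are enumerated; overlapping matches are reported.
    One match is emitted per distinct anchor tuple; its ``end`` extends over
    the longest feasible tail (at most ``tail_range[1]`` residues after the
    final glycine, and at least ``tail_range[0]`` must be available).
    Ambiguous letters (B, Z, X, U, O) never satisfy a fixed anchor but are
    accepted at gap positions.  Matching is case-insensitive.  Returns
    matches sorted by (start, end).
    """
    spec = spec or CagePatternSpec()
    seq = _validate(sequence)
    n = len(seq)
    aromatic = spec.aromatic_set
    g1_lo, g1_hi = spec.gap1_range
    g2_lo, g2_hi = spec.gap2_range
    t_lo, t_hi = spec.tail_range
    out: list[MotifMatch] = []
    # 0-based index scan; i is the first aromatic of the phi-phi-G-phi block
    for i in range(n - spec.min_length + 1):
        if seq[i] not in aromatic or seq[i + 1] not in aromatic:
            continue
        if seq[i + 2] != "G" or seq[i + 3] not in aromatic:
            continue
        for g1 in range(g1_lo, g1_hi + 1):
            p = i + 4 + g1
            if p >= n or seq[p] != "P":
                continue
            for g2 in range(g2_lo, g2_hi + 1):
                g = p + 1 + g2
                if g >= n or seq[g] != "G":
                    continue
                tail_avail = n - 1 - g
                if tail_avail < t_lo:
                    continue
                end = g + min(tail_avail, t_hi)
                out.append(
                    MotifMatch(
                        sequence_id=sequence_id,
                        start=i + 1,
                        end=end + 1,
                        anchors=(i + 1, i + 2, i + 3, i + 4, p + 1, g + 1),
                        kind="cage",
                    )
                )
    out.sort(key=lambda m: (m.start, m.end, m.anchors))
    return out


def scan_ca(
    sequence: str,
    spec: CaMotifSpec | None = None,
    sequence_id: str = "",
) -> list[MotifMatch]:
    """Find every window matching the DxDxDG-like calcium-binding loop.

    A window of six residues matches when positions 1, 3 and 5 come from the
    coordinating alphabet and position 6 is glycine.  Overlaps permitted;
    output sorted by start.
    """
    spec = spec or CaMotifSpec()
    seq = _validate(sequence)
    coord = spec.coordinating_alphabet
    out: list[MotifMatch] = []
    for i in range(len(seq) - 5):
        if (
            seq[i] in coord
            and seq[i + 2] in coord
            and seq[i + 4] in coord
            and seq[i + 5] == "G"
        ):
            out.append(
                MotifMatch(
                    sequence_id=sequence_id,
                    start=i + 1,
                    end=i + 6,
                    anchors=(i + 1, i + 3, i + 5, i + 6),
                    kind="ca",
                )
            )
    return out


@dataclass(frozen=True)
class BladeWindowParams:
    """Bounds on the sequence window a single blade may occupy.

    A blade of the integrin-type propeller is an approximately 60-residue
    unit; the defaults allow 45-80 residues.  ``seq_length`` is the length
    of the parent sequence (needed to decide whether a window fits).
    """

    lower: int = 45
    upper: int = 80
    seq_length: int = 0

    def __post_init__(self):
        if not (0 < self.lower <= self.upper):
            raise ValueError("require 0 < lower <= upper")


@dataclass(frozen=True)
class BladeCandidate:
    """A putative blade: a Cage match plus its surrounding window.

    ``span`` is the blade window anchored at the Cage match start and
    extending ``upper`` residues (clipped at the sequence end); ``cage`` is
    the Cage occurrence itself; ``ca`` an optional calcium-loop occurrence
    falling inside the window without touching Cage anchor positions.
    ``full_length`` is True when a window of at least the lower length bound
    fits inside the sequence — the sequence-level proxy for "able to
    incorporate all structural elements of the blade motif".
    """

    sequence_id: str
    span: tuple[int, int]
    cage: MotifMatch
    ca: Optional[MotifMatch]
    full_length: bool

    def __post_init__(self):
        lo, hi = self.span
        if not (lo <= self.cage.start and self.cage.end <= hi):
            raise ValueError("cage must lie within span")
        if self.ca is not None:
            if not (lo <= self.ca.start and self.ca.end <= hi):
                raise ValueError("ca must lie within span")
            if set(self.ca.anchors) & set(self.cage.anchors):
                raise ValueError("ca anchors must not overlap cage anchors")

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def build_blade_candidates(
    cage_matches: Sequence[MotifMatch],
    ca_matches: Sequence[MotifMatch],
    window_params: BladeWindowParams,
) -> list[BladeCandidate]:
    """Pair Cage matches with calcium-loop matches into blade candidates.

    One candidate is produced per Cage match.  The blade window starts at
    the Cage match and runs for the upper window bound (clipped to the
    sequence).  A Ca match is attached when it lies inside the window and
    its residues do not sit on Cage anchor positions; if several qualify the
    earliest is taken.  The relative order of the two motifs within the
    window is not constrained.
    """
    n = window_params.seq_length
    out: list[BladeCandidate] = []
    for cage in cage_matches:
        lo = cage.start
        hi = min(lo + window_params.upper - 1, n) if n else lo + window_params.upper - 1
        hi = max(hi, cage.end)
        full = (n == 0 or lo + window_params.lower - 1 <= n) and (
            hi - lo + 1 >= window_params.lower
        )
        attached = None
        anchor_set = set(cage.anchors)
        for ca in ca_matches:
            if ca.start >= lo and ca.end <= hi:
                if not (set(range(ca.start, ca.end + 1)) & anchor_set):
                    attached = ca
                    break
        out.append(
            BladeCandidate(
                sequence_id=cage.sequence_id,
                span=(lo, hi),
                cage=cage,
                ca=attached,
                full_length=full,
            )
        )
    return out


def retest_cage(subsequence: str, spec: CagePatternSpec | None = None) -> bool:
    """Re-test a matched subsequence against the Cage pattern (funnel stage 4)."""
    try:
        return bool(scan_cage(subsequence, spec))
    except SequenceAlphabetError:
        return False
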