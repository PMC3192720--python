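"""Independent brute-force oracles used to validate the fast scanners.

These deliberately take a different route from the implementation: the
motif oracles instantiate every fixed-gap pattern as a stdlib-``re``
expression and full-match it against every window, and the chaining oracle
enumerates candidate subsets exhaustively.
"""

from __future__ import annotations

import itertools
import re

from fggap.patterns import BladeCandidate, CagePatternSpec, CaMotifSpec


def cage_oracle(seq: str, spec: CagePatternSpec | None = None):
    """Exhaustive window/anchor enumeration of the Cage pattern.

    Returns the set of (start, anchors, end) triples (1-based) the scanner
    must produce: one entry per distinct anchor placement, with the end
    extended over the longest feasible tail.
    """
    spec = spec or CagePatternSpec()
    seq = seq.upper()
    n = len(seq)
    aro = "".join(sorted(spec.aromatic_set))
    found = set()
    for i in range(n):
        for g1 in range(spec.gap1_range[0], spec.gap1_range[1] + 1):
            for g2 in range(spec.gap2_range[0], spec.gap2_range[1] + 1):
                core = 4 + g1 + 1 + g2 + 1
                window = seq[i : i + core]
                if len(window) < core:
                    continue
                pat = f"[{aro}][{aro}]G[{aro}].{{{g1}}}P.{{{g2}}}G"
                if not re.fullmatch(pat, window):
                    continue
                tail_avail = n - (i + core)
                if tail_avail < spec.tail_range[0]:
                    continue
                end = i + core + min(tail_avail, spec.tail_range[1])
                anchors = (
                    i + 1, i + 2, i + 3, i + 4,
                    i + 4 + g1 + 1, i + 4 + g1 + 1 + g2 + 1,
                )
                found.add((i + 1, anchors, end))
    return found


def ca_oracle(seq: str, spec: CaMotifSpec | None = None):
    """Overlapping-window regex oracle for the DxDxDG pattern."""
    spec = spec or CaMotifSpec()
    seq = seq.upper()
    coord = "".join(sorted(spec.coordinating_alphabet))
    pat = re.compile(f"(?=([{coord}].[{coord}].[{coord}]G))")
    return {(m.start() + 1, m.start() + 6) for m in pat.finditer(seq)}


def chain_oracle(candidates, min_start=45, max_linker=400):
    """Maximum chain size by exhaustive subset enumeration (<= ~12 candidates)."""

    def valid(subset):
        subset = sorted(subset, key=lambda c: c.start)
        for a, b in zip(subset, subset[1:]):
            d = b.start - a.start
            if d < min_start or d > max_linker:
                return False
            if not (a.cage.end < b.cage.start or b.cage.end < a.cage.start):
                return False
        return True

    best = 0
    cands = list(candidates)
    for r in range(len(cands), 0, -1):
        if r <= best:
            break
        for subset in itertools.combinations(cands, r):
            if valid(subset):
                best = r
                break
    return best


def random_protein_sequence(rng, length: int) -> str:
    letters = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(letters[i] for i in rng.integers(0, 20, size=length))
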