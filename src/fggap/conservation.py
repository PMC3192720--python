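"""Position-frequency statistics over aligned blade repeats.

Given equal-length rows of aligned blade sequences (gap symbol ``-``), the
profile tallies per-column amino-acid counts, from which position
probabilities (e.g. the probability of glycine at motif position A3),
dominance ratios (how many times more frequent the top residue is than any
other), consensus strings and per-column information content are derived.
Gaps are excluded from denominators: reported values are residue
probabilities among observed residues, not gap-inclusive frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")
OTHER = "other"
GAP = "-"


@dataclass
class ConservationProfile:
    """Per-position amino-acid count matrix over aligned repeats.

    ``counts`` is a DataFrame indexed by position label with one column per
    standard residue plus ``other`` (non-standard letters) and ``gap``.
    """

    counts: pd.DataFrame
    n_sequences: int

    @property
    def positions(self) -> list[str]:
        return list(self.counts.index)

    def non_gap(self, position: str) -> int:
        row = self._row(position)
        return int(row[AA_ORDER + [OTHER]].sum())

    def _row(self, position: str) -> pd.Series:
        if position not in self.counts.index:
            raise KeyError(f"unknown position {position!r}")
        return self.counts.loc[position]

    def frequencies(self, position: str) -> pd.Series:
        """Residue frequencies at a position over non-gap observations."""
        row = self._row(position)[AA_ORDER + [OTHER]]
        total = row.sum()
        if total == 0:
            return row.astype(float)
        return row / total

    def merge(self, other: "ConservationProfile") -> "ConservationProfile":
        if list(self.counts.index) != list(other.counts.index):
            raise ValueError("profiles have different position labels")
        return ConservationProfile(
            counts=self.counts + other.counts,
            n_sequences=self.n_sequences + other.n_sequences,
        )

    def information_content(self, position: str) -> float:
        """Shannon information content in bits: log2(20) - H(column)."""
        freqs = self.frequencies(position)[AA_ORDER]
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        return math.log2(20) - entropy

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def build_profile(
    aligned_rows: Sequence[str],
    position_labels: Optional[Sequence[str]] = None,
) -> ConservationProfile:
    """Tally per-column residue counts from equal-length aligned rows.

    Rows must share one length; a ragged row raises with its index.
    Standard letters are counted under themselves, ``-`` under ``gap``,
    everything else under ``other``.
    """
    rows = [r.upper() for r in aligned_rows]
    if not rows:
        raise ValueError("no rows given")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(
                f"row {i} has length {len(r)}, expected {width} (ragged alignment)"
            )
    if position_labels is None:
        position_labels = [str(i + 1) for i in range(width)]
    elif len(position_labels) != width:
        raise ValueError("position_labels length must equal alignment width")
    columns = AA_ORDER + [OTHER, "gap"]
    data = np.zeros((width, len(columns)), dtype=int)
    col_index = {aa: j for j, aa in enumerate(columns)}
    for r in rows:
        for i, letter in enumerate(r):
            if letter in col_index:
                data[i, col_index[letter]] += 1
            elif letter == GAP:
                data[i, col_index["gap"]] += 1
            else:
                data[i, col_index[OTHER]] += 1
    counts = pd.DataFrame(data, index=list(position_labels), columns=columns)
    return ConservationProfile(counts=counts, n_sequences=len(rows))


def position_probability(
    profile: ConservationProfile, position: str, residue: str
) -> float:
    """P(residue at position) among non-gap observations."""
    residue = residue.upper()
    row = profile._row(position)
    total = profile.non_gap(position)
    if total == 0:
        return 0.0
    key = residue if residue in AA_ORDER else OTHER
    return float(row[key]) / total


def dominance_ratio(
    profile: ConservationProfile, position: str, residue: str
) -> float:
    """Frequency of ``residue`` over the max frequency of any other residue.

    Returns ``inf`` when no other residue is observed at the position (the
    flagged maximum for an invariant column).
    """
    residue = residue.upper()
    row = profile._row(position)[AA_ORDER + [OTHER]]
    key = residue if residue in AA_ORDER else OTHER
    own = float(row[key])
    others = row.drop(key)
    top_other = float(others.max()) if len(others) else 0.0
    if top_other == 0:
        return math.inf
    return own / top_other


def consensus_sequence(
    profile: ConservationProfile,
    threshold: float = 0.5,
    wildcard: str = "x",
) -> tuple[str, list[str]]:
    """Per-column majority consensus at a frequency threshold.

    Returns ``(consensus, tied_positions)``: a column contributes its
    majority residue when that residue's non-gap frequency reaches the
    threshold, else the wildcard.  Ties are broken alphabetically and the
    position label recorded in ``tied_positions``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    letters = []
    ties = []
    for pos in profile.positions:
        freqs = profile.frequencies(pos)[AA_ORDER]
        if float(freqs.sum()) == 0.0:
            letters.append(wildcard)
            continue
        top = float(freqs.max())
        winners = sorted(freqs[freqs == top].index)
        if len(winners) > 1:
            ties.append(pos)
        letters.append(winners[0] if top >= threshold else wildcard)
    return "".join(letters), ties
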