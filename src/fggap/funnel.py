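"""Seven-fold repeat chaining and the four-stage filtering funnel.

A sequence hosting an integrin-type beta-propeller domain must carry seven
consecutive blade repeats, each with the Cage signature.  This module
chains blade candidates into non-overlapping repeat arrays and applies a
staged filter over a sequence collection:

stage 1  at least one blade signature;
stage 2  at least seven chained signatures;
stage 3  seven chained candidates, all full-length;
stage 4  the Cage motif re-confirmed in each of the seven repeats.

Stage counts are monotonically non-increasing by construction.  Sequences
with ~14 chained signatures are flagged as tandem domain copies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .patterns import (
    BladeCandidate,
    BladeWindowParams,
    CagePatternSpec,
    CaMotifSpec,
    MotifMatch,
    build_blade_candidates,
    retest_cage,
    scan_ca,
    scan_cage,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpacingBounds:
    """Constraints on consecutive blade starts within one repeat array.

    ``min_start`` / ``max_start`` bound the start-to-start spacing of
    consecutive blades in a compact domain (a blade is roughly 60 residues
    plus loop-length variability).  Spacings up to ``max_linker`` are still
    chained — they accommodate the linker between two tandem propeller
    domains — but are recorded as linkers.
    """

    min_start: int = 45
    max_start: int = 120
    max_linker: int = 400

    def __post_init__(self):
        if not (0 < self.min_start <= self.max_start <= self.max_linker):
            raise ValueError("require 0 < min_start <= max_start <= max_linker")


@dataclass(frozen=True)
class RepeatArray:
    """An ordered chain of non-overlapping blade candidates from one sequence."""

    sequence_id: str
    blades: tuple[BladeCandidate, ...]

    @property
    def n_blades(self) -> int:
        return len(self.blades)

    @property
    def span(self) -> tuple[int, int]:
        return (self.blades[0].start, self.blades[-1].end)


@dataclass(frozen=True)
class ArchitectureCall:
    """Domain-architecture call for one sequence.

    ``call`` is one of ``none``, ``partial`` (1 <= k < 7 chained blades),
    ``single_domain`` (>= 7) or ``tandem`` (>= 14, two tandem propellers).
    """

    sequence_id: str
    call: str
    n_signatures: int

    def __post_init__(self):
        if self.call == "tandem" and self.n_signatures < 14:
            raise ValueError("tandem requires >= 14 chained blades")
        if self.call == "single_domain" and self.n_signatures < 7:
            raise ValueError("single_domain requires >= 7 chained blades")


def _overlap(a: BladeCandidate, b: BladeCandidate) -> bool:
    # overlap is judged on the Cage match extents: blade windows are
    # deliberately generous (upper bound) and would collide for compact
    # domains even when the blades themselves are distinct
    return not (a.cage.end < b.cage.start or b.cage.end < a.cage.start)


def chain_repeats(
    candidates: Sequence[BladeCandidate],
    spacing: SpacingBounds | None = None,
) -> list[RepeatArray]:
    """Chain blade candidates into maximal repeat arrays.

    Dynamic programming over candidates sorted by start position finds a
    maximum-cardinality chain of pairwise non-overlapping candidates whose
    consecutive start-to-start spacings lie within
    ``[min_start, max_linker]``; ties are broken toward the earliest
    (smallest) total span.  The winning chain is then split into one
    :class:`RepeatArray` per run of spacings ``<= max_linker`` (a single
    array may bridge a tandem linker; arrays are only split where chaining
    itself breaks).
    """
    spacing = spacing or SpacingBounds()
    if not candidates:
        return []
    cands = sorted(candidates, key=lambda c: (c.start, c.end))
    n = len(cands)
    # dp over chains ending at i: (length, total_span, start_tuple_for_ties)
    best_len = [1] * n
    best_span = [c.end - c.start + 1 for c in cands]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            d = cands[i].start - cands[j].start
            if d < spacing.min_start or d > spacing.max_linker:
                continue
            if _overlap(cands[j], cands[i]):
                continue
            cand_len = best_len[j] + 1
            cand_span = best_span[j] + (cands[i].end - cands[i].start + 1)
            if cand_len > best_len[i] or (
                cand_len == best_len[i] and cand_span < best_span[i]
            ):
                best_len[i] = cand_len
                best_span[i] = cand_span
                prev[i] = j
    # pick chain of max length; tie -> smallest total span, then earliest end
    order = sorted(
        range(n), key=lambda i: (-best_len[i], best_span[i], cands[i].end)
    )
    i = order[0]
    chain: list[BladeCandidate] = []
    while i != -1:
        chain.append(cands[i])
        i = prev[i]
    chain.reverse()
    sequence_id = chain[0].sequence_id
    arrays: list[RepeatArray] = []
    run: list[BladeCandidate] = [chain[0]]
    for prev_c, cur in zip(chain, chain[1:]):
        if cur.start - prev_c.start > spacing.max_linker:
            arrays.append(RepeatArray(sequence_id, tuple(run)))
            run = [cur]
        else:
            run.append(cur)
    arrays.append(RepeatArray(sequence_id, tuple(run)))
    return arrays


def call_architecture(arrays: Sequence[RepeatArray], sequence_id: str = "") -> ArchitectureCall:
    """Call the domain architecture from the chained repeat arrays."""
    if arrays:
        sequence_id = sequence_id or arrays[0].sequence_id
    best = max((a.n_blades for a in arrays), default=0)
    if best >= 14:
        call = "tandem"
    elif best >= 7:
        call = "single_domain"
    elif best >= 1:
        call = "partial"
    else:
        call = "none"
    return ArchitectureCall(sequence_id=sequence_id, call=call, n_signatures=best)


@dataclass
class FunnelConfig:
    cage_spec: CagePatternSpec = field(default_factory=CagePatternSpec)
    ca_spec: CaMotifSpec = field(default_factory=CaMotifSpec)
    window: BladeWindowParams = field(default_factory=BladeWindowParams)
    spacing: SpacingBounds = field(default_factory=SpacingBounds)
    min_blades: int = 7


@dataclass
class FunnelReport:
    """Per-stage survivor ledger of the filtering funnel."""

    stage1: list[str] = field(default_factory=list)
    stage2: list[str] = field(default_factory=list)
    stage3: list[str] = field(default_factory=list)
    stage4: list[str] = field(default_factory=list)
    architecture: dict[str, ArchitectureCall] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.stage1), len(self.stage2), len(self.stage3), len(self.stage4))

    def to_dict(self) -> dict:
        return {
            "counts": dict(
                zip(("stage1", "stage2", "stage3", "stage4"), self.counts)
            ),
            "stage1": self.stage1,
            "stage2": self.stage2,
            "stage3": self.stage3,
            "stage4": self.stage4,
            "architecture": {
                k: {"call": v.call, "n_signatures": v.n_signatures}
                for k, v in self.architecture.items()
            },
            "notes": self.notes,
        }


def parse_hmmer_domtbl(path) -> dict[str, list[tuple[int, int]]]:
    """Parse a HMMER3 ``--domtblout`` per-domain table.

    Returns a mapping from target sequence name to the list of alignment
    coordinate spans (``ali from``/``ali to`` columns, 1-based closed).
    Only the whitespace-delimited fixed columns are used; the free-text
    description is ignored.
    """
    hits: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 23:
                raise ValueError(
                    f"malformed HMMER domtblout line {line_no}: "
                    f"expected >= 23 columns, got {len(parts)}"
                )
            target = parts[0]
            ali_from, ali_to = int(parts[17]), int(parts[18])
            hits.setdefault(target, []).append((ali_from, ali_to))
    for spans in hits.values():
        spans.sort()
    return hits


def analyze_record(
    sequence_id: str,
    sequence: str,
    config: FunnelConfig,
    hmmer_spans: Optional[Sequence[tuple[int, int]]] = None,
) -> dict:
    """Scan one sequence and chain its blade candidates.

    When ``hmmer_spans`` is given (per-domain hits for this sequence from an
    external profile search), the internal Cage scanner is restricted to
    those spans for signature calling; otherwise the whole sequence is
    scanned.
    """
    window = BladeWindowParams(
        lower=config.window.lower,
        upper=config.window.upper,
        seq_length=len(sequence),
    )
    cage = scan_cage(sequence, config.cage_spec, sequence_id)
    if hmmer_spans is not None:
        cage = [
            m
            for m in cage
            if any(lo <= m.start and m.end <= hi for lo, hi in hmmer_spans)
        ]
    ca = scan_ca(sequence, config.ca_spec, sequence_id)
    cands = build_blade_candidates(cage, ca, window)
    arrays = chain_repeats(cands, config.spacing)
    arch = call_architecture(arrays, sequence_id)
    return {
        "cage_matches": cage,
        "ca_matches": ca,
        "candidates": cands,
        "arrays": arrays,
        "architecture": arch,
    }


def run_funnel(
    records: Iterable[tuple[str, str]],
    config: FunnelConfig | None = None,
    hmmer_hits: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> FunnelReport:
    """Apply the four-stage filter to a collection of (id, sequence) records.

    The stages are applied in order per record and the report lists the
    survivors of each; every stage-k survivor is a stage-(k-1) survivor, so
    counts are non-increasing.  Records whose ids are missing from
    ``hmmer_hits`` (when one is supplied) fall back to the internal scanner
    with a warning.
    """
    config = config or FunnelConfig()
    report = FunnelReport()
    for sequence_id, sequence in records:
        spans = None
        if hmmer_hits is not None:
            if sequence_id in hmmer_hits:
                spans = hmmer_hits[sequence_id]
            else:
                msg = (
                    f"sequence {sequence_id!r} absent from HMMER table; "
                    "falling back to internal scanner"
                )
                warnings.warn(msg)
                report.notes.append(msg)
        res = analyze_record(sequence_id, sequence, config, spans)
        arch = res["architecture"]
        report.architecture[sequence_id] = arch
        if arch.n_signatures < 1:
            continue
        report.stage1.append(sequence_id)
        if arch.n_signatures < config.min_blades:
            continue
        report.stage2.append(sequence_id)
        # stage 3: a chain of >= 7 candidates, all full-length
        full = [c for c in res["candidates"] if c.full_length]
        full_arrays = chain_repeats(full, config.spacing) if full else []
        best_full = max((a.n_blades for a in full_arrays), default=0)
        if best_full < config.min_blades:
            continue
        best_arr = max(full_arrays, key=lambda a: a.n_blades)
        report.stage3.append(sequence_id)
        # stage 4: Cage motif re-confirmed on each chained candidate's
        # matched subsequence
        seq = sequence.upper()
        ok = 0
        for blade in best_arr.blades:
            sub = seq[blade.cage.start - 1 : blade.cage.end]
            if retest_cage(sub, config.cage_spec):
                ok += 1
        if ok >= config.min_blades:
            report.stage4.append(sequence_id)
    return report
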