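# Methods

This note records the models, conventions and design decisions behind
`fggap`, in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and what the synthetic benchmarks do and
do not demonstrate.

## Coordinates and conventions

All sequence coordinates are 1-based closed intervals, everywhere.
Structure handling uses author residue numbering end-to-end, takes the
first model of multi-model files, and resolves alternate locations to the
highest-occupancy conformer. Angles are reported in degrees in (−180, 180].

## Motif scanners

The Cage consensus `φφGφ X13–20 P X2–15 G X5–8` has four bounded gaps, so
matching is implemented as exact enumeration over anchor placements rather
than regular-expression search: for every aromatic pair the scanner tests
the glycine and aromatic anchors, then every admissible spacer width to the
proline and final glycine. One match is reported per distinct anchor tuple;
its end extends over the longest feasible tail (5–8 residues after the
final glycine), which keeps match lengths within the arithmetic bounds
26–49. Every placement is reported — overlaps included — because greedy or
leftmost-only matching can destroy valid seven-blade chains downstream.

Defaults: φ = {F, W, Y}. Histidine is excluded (the FG pair of the FG-GAP
description implies phenylalanine dominance) but the aromatic set is
configurable. Ambiguous input letters (B, Z, X, U, O) are tolerated at gap
positions and never satisfy a fixed anchor. Matching is case-insensitive.

The DxDxDG scanner accepts {D, N} at the three coordinating positions by
default — asparagine substitutions are common in this loop family — with a
strict-aspartate mode available. The terminal glycine is mandatory.

The test suite re-derives both scanners' outputs with an independent
brute-force oracle (stdlib-`re` full matching of every gap-instantiated
pattern against every window) and requires set equality.

## Blade candidates and chaining

A blade candidate anchors a window of 45–80 residues (centred on the
~60-residue repeat unit) at each Cage match. A Ca-loop match is attached
when it falls inside the window without sitting on a Cage anchor; the
relative order of the two motifs within the blade is deliberately left
unconstrained, since the linear arrangement of the calcium loops relative
to segments A/B/C varies. A candidate is *full-length* when a window of at
least the lower bound fits inside the sequence — the sequence-level proxy
for "able to incorporate all structural elements of the motif".

Chaining maximizes the *count* of non-overlapping candidates (the domain
criterion is a count threshold, ≥7, not a score), by dynamic programming
over candidates sorted by start, with ties broken toward the smallest total
span. Overlap is judged on the Cage match extents rather than the generous
blade windows, which would collide for compact domains. Consecutive starts
must be 45–120 residues apart within a compact domain; spacings up to 400
residues are still chained to accommodate the linker between two tandem
propellers. For ≤12 candidates the chain is verified in tests against
exhaustive subset enumeration.

Architecture calls: ≥14 chained blades → `tandem`, ≥7 → `single_domain`,
1–6 → `partial`, else `none`.

## The filtering funnel

Stage 1 keeps sequences with at least one signature (a Cage match inside a
blade window); stage 2 requires at least seven *chained* signatures (raw
match counts would double-count one blade's alternative placements);
stage 3 requires a chain of seven candidates that are all full-length;
stage 4 re-tests the matched Cage subsequence of each of the seven.
Survivor lists are nested by construction, so the stage counts are
monotonically non-increasing for any input. An optional HMMER3
`--domtblout` table can restrict stage-1/2 signature calling to externally
detected domain hits; records missing from the table fall back to the
internal scanner with a warning.

## Torsions, turns, hydrogen bonds, calcium sites

φ(i) = C(i−1)–N(i)–CA(i)–C(i) and ψ(i) = N(i)–CA(i)–C(i)–N(i+1), computed
with the standard projection formula (cross-checked against gemmi's
dihedral in tests). Chain-terminal residues, residues with missing backbone
atoms, and residues flanking a chain break (C–N > 2.5 Å) carry an explicit
undefined marker, never 0.

β-turn typing compares (φ₂, ψ₂, φ₃, ψ₃) of a four-residue window against
canonical values — type I (−60, −30, −90, 0), type II (−60, 120, 90, 0),
their primes, VIa1, VIb, VIII — under the conventional tolerance of ±30°
per angle with a single angle allowed ±45°. A *nearest type* (argmin of the
maximal circular deviation) is always reported alongside the strict
assignment, so that distorted turns ("non-standard, but more typical of
type II") remain representable: e.g. the window (−57, 163, 64, 32)
classifies strict-none / nearest-II. The chain-reversal criterion is
CA1–CA4 ≤ 7 Å and the turn's own hydrogen bond O(1)···N(4) ≤ 3.5 Å. The
tolerances are declared defaults, configurable per definition.

Hydrogen bonds are geometric, not energetic: main-chain N→O pairs among the
annotated segment residues with N···O ≤ 3.5 Å and, when the amide hydrogen
is inferable from the preceding carbonyl, an N–H···O angle ≥ 120°; sequence
neighbours (|i−j| < 2) are excluded. Bonds are labelled by segment pair
(A–B, A–C, B–C, within-segment) and the two O(1)···N(4) turn bonds are
flagged `intra_turn`; the blade network criterion counts the inter-segment
bonds (default threshold 5, i.e. 7 bonds in total with the two turn bonds).

Ca²⁺ sites: the ligand shell is every oxygen (protein or water) within
3.0 Å of the ion — the standard Ca–O coordination distance; a *bridging
water* must lie within 3.2 Å of the ion and within 3.5 Å of a main-chain O
or N of a glycine in the 3,4-loop, the contact that couples the blade's two
calcium loops.

Blade segmentation is supplied by an annotation sidecar TSV (chain, blade,
element, start, end); automatic blade detection from geometry is out of
scope. Characteristic 5 (ring closure) is detected as a CA–CA pairing
(≤ 5.5 Å over ≥ 3 consecutive residue pairs, parallel or antiparallel)
between the segment N-terminal to blade 1 and strand 3 of blade 7.

## Conservation profiles

Column counts run over the 20 standard letters plus an `other` bucket; gaps
are excluded from denominators, because the quantities of interest are
residue probabilities among observed residues. The dominance ratio of a
residue is its frequency over the maximum frequency of any other residue,
reported as a flagged infinity for invariant columns. Consensus calling
takes the majority residue at a threshold, breaks ties alphabetically and
flags them. Information content is log₂20 − H (Shannon, bits), with no
small-sample correction. Alignments are inputs; no aligner is included.

## Synthetic data: what it emulates, what it does not

The generator's defaults are the study conditions of the analyses: blades
of 50–70 residues (uniform), each opening with a Cage block whose gaps are
drawn uniformly from the pattern ranges; a DxDxDG loop planted in every
blade (`ca_motif_rate` 1.0 — the architecture of the bacterial seven-repeat
proteins; human integrins carry the loop in only three or four blades);
seven blades joined by 5–40-residue linkers (giving start-to-start spacings
of 55–110 residues), a 150–250-residue linker between tandem domains, and
5–30-residue terminal extensions; a uniform background over the 20 letters,
chosen over an integrin-like composition so that false-positive rates stay
interpretable. `fidelity` is the per-anchor probability of planting the
motif letter intact; an unfaithful anchor is replaced by a letter that
cannot match. Decoys are shuffled positives; partial-repeat and
Cage-without-Ca records probe individual funnel stages. Exact-recovery
tests use a *clean* configuration whose background excludes the anchor
letters, so planted placements are the only placements.

Coordinate generation covers four-residue turn windows and small
constructed sites, built from ideal bond geometry (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, ω = 180°) by natural-extension placement;
recomputing torsions on such a backbone reproduces the requested angles to
better than 1e-4°. The synthetic blade assembly realizes the two turns with
correct geometry and *places* the flanking segment residues so that exactly
five inter-segment N···O contacts exist; it is a fixture for the detectors'
bookkeeping, not a physical model. No full propeller structures are
generated.

Passing the synthetic suites therefore demonstrates correctness of the
scanners, chaining, funnel logic and geometric detectors under planted
truth — it does not by itself demonstrate sensitivity or specificity on
real proteomes, where composition bias, long insertions in blades (e.g. the
αI domain inserted between blades 2 and 3 of half the human α subunits) and
divergent loop lengths matter.

## Reference-structure checks

Four acceptance tests validate the torsion engine, the turn-exception
calls, the per-blade H-bond count and the A3/B2 conservation statistics
against the deposited αVβ3 and αIIbβ3 ectodomain structures and a curated
126-blade table of the 18 human α subunits. Those third-party inputs are
not redistributed; `data/reference/README.md` documents how to supply them.
Without the files the four tests fail with an explanatory message rather
than silently skipping, so their status is always visible.

## Problem sizes

The self-contained benchmarks use 100-record collections (10 positives, 20
three-blade partials, 70 decoys), 200 random sequences of up to 200
residues for oracle equivalence, 100–200 records per fidelity level for the
detection curve, and 126 blades for generator-parameter recovery — sizes at
which the brute-force oracles remain exact and the whole suite runs in
seconds.

## Known limitations

* Stage-3 "full-length" is a declared sequence-window approximation of a
  verbal structural criterion.
* Blade windows anchor at the Cage match start; motifs far upstream of the
  aromatic block would be missed by candidate attachment.
* H-bond detection has no energy model and, without an inferable amide
  hydrogen, reduces to a distance criterion.
* Turn-type tolerances for structure-wide classification are declared, not
  fitted.
* No automatic blade segmentation, no profile-HMM of the FG-GAP family, no
  multiple-sequence alignment, and no taxonomic post-processing.
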