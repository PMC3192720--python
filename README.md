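# fggap

Detection and structural validation of **integrin-type 7-bladed
β-propeller blades** — the FG-GAP/Cage repeat domains of integrin
α subunits and their homologues in bacterial proteomes.

## The problem

The N-terminal domain of every integrin α subunit folds into a seven-bladed
β-propeller. Each ~60-residue blade is a four-stranded antiparallel β-sheet
whose loop segments A (residues A0–A4), B (B0–B4) and C (C1, C2) carry the
conserved letters of two overlapping sequence motifs:

* the **Cage / FG-GAP consensus** `φφGφ X13–20 P X2–15 G X5–8`
  (φ = aromatic, X = any residue), and
* a **DxDxDG-like Ca²⁺-binding loop** at the opposite end of the blade,
  bridged to the 3,4-loop through a conserved water molecule.

These sequence signatures are the shadow of a structural motif: segment A
folds into a type II β-turn (canonical torsions φ₂ = −60°, ψ₂ = +120°,
φ₃ = +90°, ψ₃ = 0°, hence the near-invariant glycine at A3), segment B into
a type I β-turn (φ₂ = −60°, ψ₂ = −30°, φ₃ = −90°, ψ₃ = 0°, hence the
proline at B2), and the two turns are cross-linked by five inter-segment
main-chain hydrogen bonds (seven in total, counting the two O(1)···N(4)
bonds internal to the turns). Five characteristics — Cage motif, paired
II/I turns, the H-bond network, the Ca²⁺ motif, and the ring-closing
non-sequential fourth strand of blade 7 — distinguish this superfamily from
the other thirteen seven-bladed propeller superfamilies.

`fggap` operationalizes both levels for people hunting these domains in
sequence databases or validating them in structures:

* **sequence level** — variable-gap scanners that enumerate *every* anchor
  placement of the two motifs, blade-candidate construction, dynamic
  programming chaining into seven-fold (or tandem fourteen-fold) repeat
  arrays, and a four-stage filtering funnel over a FASTA collection
  (≥1 signature → ≥7 chained signatures → 7 full-length segments → Cage
  confirmed in all seven);
* **structure level** — backbone φ/ψ computation, β-turn typing with a
  strict tolerance gate (±30° per angle, one angle ±45°) and a nearest-type
  fallback, geometric main-chain H-bond detection, Ca²⁺-site coordination
  checks, and per-blade / per-domain verdicts over the five
  characteristics;
* **conservation** — position-frequency profiles over aligned blades,
  position probabilities, dominance ratios, consensus strings and
  per-column information content;
* **synthetic data** — a seeded generator of proteins with planted blades
  (tunable anchor fidelity and Ca-loop rate), decoys, and ideal-geometry
  backbones for prescribed torsions, so the whole pipeline is testable
  without any downloads.

## Worked example

Scan a sequence for the two motifs:

```python
from fggap import scan_cage, scan_ca

seq = "AAAFYGW" + "A" * 13 + "P" + "AA" + "G" + "AAAAA"
for m in scan_cage(seq):
    print("cage", m.start, m.end, m.anchors)
for m in scan_ca("DVDADGKDNDTDG"):
    print("ca", m.start, m.end)
```

prints

```
cage 4 29 (4, 5, 6, 7, 21, 24)
ca 1 6
ca 8 13
```

— one Cage placement spanning residues 4–29 with its six fixed anchors
(φ, φ, G, φ at 4–7, P at 21, G at 24), and two overlapping DxDxDG windows.

Generate a labelled benchmark and run the funnel from the shell:

```bash
fggap simulate --n-pos 3 --n-partial 2 --n-decoy 5 --seed 11 \
      --out bench.fasta --labels labels.tsv
fggap funnel --fasta bench.fasta --out-report report.json
```

```
10 records -> bench.fasta, labels -> labels.tsv
funnel attrition: 10 records -> 5 (>=1 signature) -> 3 (>= 7 chained) -> 3 (full-length) -> 3 (Cage confirmed)
```

The three planted seven-blade positives survive every stage; the two
three-blade partials stop after stage 1 (they carry signatures but not
seven of them); the five shuffled decoys carry none. `report.json` holds
the per-stage survivor lists and per-record architecture calls
(`single_domain` / `tandem` / `partial` / `none`).

Validate an annotated structure (PDB/mmCIF plus a blade-segment sidecar
TSV):

```bash
fggap verify-structure --structure domain.pdb --annotation blades.tsv --mode strict
```

which reports, per blade, the four characteristic booleans, the
inter-segment H-bond count, and the assigned turn types (a `~II` marks a
nearest-type fallback where the strict gate failed).

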