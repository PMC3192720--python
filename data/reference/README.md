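# Reference data (not redistributed)

Four acceptance checks in `tests/test_acceptance.py` validate the geometry
engines against deposited crystal structures of human integrin ectodomains
and a curated blade table. Those inputs are third-party data and are not
shipped with the package. To run the checks, place the following files in
this directory:

| file | content |
| --- | --- |
| `1JV2.pdb` | alphaV-beta3 ectodomain (PDB 1JV2, https://files.rcsb.org/download/1JV2.pdb) |
| `2VDR.pdb` | alphaIIb-beta3 ectodomain (PDB 2VDR, https://files.rcsb.org/download/2VDR.pdb) |
| `1JV2_blades.tsv` | blade annotation sidecar for the alphaV propeller (chain A), format below |
| `2VDR_blades.tsv` | blade annotation sidecar for the alphaIIb propeller (chain A) |
| `human_blade_table.tsv` | one row per blade of the 18 human alpha subunits (126 rows) with at least columns `A3` and `B2` holding the one-letter residue at those motif positions |

The sidecar format is the annotation TSV read by
`fggap.structure.read_annotation`: tab-separated columns
`chain  blade  element  start  end`, with `element` one of
`strand1..strand4`, `A0..A4`, `B0..B4`, `C1`, `C2`, `caloop12`, `caloop34`,
`ca_ion` and residue numbers in author numbering. Without these files the
four reference checks fail with an explanatory message; every other test is
self-contained.
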