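"""File I/O: FASTA records, match/report tables, structure export."""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .patterns import BladeCandidate, MotifMatch
from .structure import ChainModel


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Returns (id, sequence) pairs; trailing ``*`` stop symbols are stripped.
    A file with no parseable record raises with the record index.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).strip().rstrip("*").replace("*", "")
        if not rec.id:
            raise ValueError(f"FASTA record {i} has no identifier")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def matches_to_frame(
    matches: Sequence[MotifMatch], sequences: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate motif matches (one row per match) for TSV export."""
    rows = []
    for m in matches:
        sub = ""
        if sequences and m.sequence_id in sequences:
            sub = sequences[m.sequence_id][m.start - 1 : m.end]
        rows.append(
            {
                "sequence_id": m.sequence_id,
                "kind": m.kind,
                "start": m.start,
                "end": m.end,
                "anchors": ",".join(map(str, m.anchors)),
                "matched": sub,
            }
        )
    return pd.DataFrame(
        rows, columns=["sequence_id", "kind", "start", "end", "anchors", "matched"]
    )


def candidates_to_frame(cands: Sequence[BladeCandidate]) -> pd.DataFrame:
    rows = [
        {
            "sequence_id": c.sequence_id,
            "start": c.start,
            "end": c.end,
            "cage_start": c.cage.start,
            "cage_end": c.cage.end,
            "ca_start": c.ca.start if c.ca else "",
            "ca_end": c.ca.end if c.ca else "",
            "full_length": c.full_length,
        }
        for c in cands
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "start", "end", "cage_start", "cage_end",
            "ca_start", "ca_end", "full_length",
        ],
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def chain_to_pdb(chain: ChainModel, path) -> None:
    """Write a ChainModel to a minimal PDB file via gemmi."""
    import gemmi

    st = gemmi.Structure()
    st.name = "fggap"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain.chain_id)
    for res in chain.residues:
        r = gemmi.Residue()
        r.name = res.name
        r.seqid = gemmi.SeqId(res.seqid, " ")
        for aname, coord in res.atoms.items():
            a = gemmi.Atom()
            a.name = aname
            a.element = gemmi.Element(res.elements.get(aname, aname[0]))
            a.pos = gemmi.Position(*map(float, coord))
            a.occ = 1.0
            r.add_atom(a)
        ch.add_residue(r)
    model.add_chain(ch)
    het = gemmi.Chain("Z")
    for seqid, (element, coord) in chain.ions.items():
        r = gemmi.Residue()
        r.name = element
        r.seqid = gemmi.SeqId(seqid, " ")
        r.het_flag = "H"
        a = gemmi.Atom()
        a.name = element
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*map(float, coord))
        a.occ = 1.0
        r.add_atom(a)
        het.add_residue(r)
    for wi, w in enumerate(chain.waters):
        r = gemmi.Residue()
        r.name = "HOH"
        r.seqid = gemmi.SeqId(9000 + wi, " ")
        r.het_flag = "H"
        a = gemmi.Atom()
        a.name = "O"
        a.element = gemmi.Element("O")
        a.pos = gemmi.Position(*map(float, w))
        a.occ = 1.0
        r.add_atom(a)
        het.add_residue(r)
    if len(het) > 0:
        model.add_chain(het)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
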