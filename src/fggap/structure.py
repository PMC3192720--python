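"""Structural validation of the integrin-blade motif on 3-D coordinates.

Each blade of the integrin-type beta-propeller is a four-stranded
antiparallel sheet whose loop segments A (five residues A0-A4), B (B0-B4)
and C (C1, C2) fold into two interlocked beta-turns — a type II turn in
segment A and a type I turn in segment B — cross-linked by a conserved
network of main-chain hydrogen bonds, with a DxDxDG calcium site bridging
the loops at the opposite end of the sheet.  Five characteristics
operationalize this:

1. the Cage sequence motif is present in the blade;
2. segment A hosts a type II and segment B a type I beta-turn;
3. an inter-segment main-chain H-bond network links A, B and C;
4. the calcium-binding motif is present (and, when an ion is bound, its
   coordination geometry verifies);
5. (domain level) the fourth strand of blade 7 arises from sequence
   N-terminal to blade 1, locking the propeller ring.

Blade segmentation is supplied via an annotation sidecar (author residue
numbering); automatic blade detection from geometry is out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

try:
    import gemmi
except ImportError:  # pragma: no cover
    gemmi = None

from .patterns import CagePatternSpec, CaMotifSpec, scan_ca, scan_cage

logger = logging.getLogger(__name__)

PEPTIDE_BOND_MAX = 2.5  # Angstrom; C(i)-N(i+1) beyond this is a chain break


# ---------------------------------------------------------------------------
# light-weight structure model


@dataclass
class Residue:
    """One residue with author numbering and a name -> coordinate atom map."""

    seqid: int
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    elements: dict[str, str] = field(default_factory=dict)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclass
class ChainModel:
    """Polymer residues of one chain plus nearby heteroatoms (ions, waters)."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    waters: list[np.ndarray] = field(default_factory=list)
    ions: dict[int, tuple[str, np.ndarray]] = field(default_factory=dict)

    def by_seqid(self) -> dict[int, Residue]:
        return {r.seqid: r for r in self.residues}

    @property
    def sequence(self) -> str:
        """One-letter sequence in residue order (X for non-standard)."""
        return "".join(_three_to_one(r.name) for r in self.residues)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name.upper(), "X")


def load_structure(path):
    """Read a PDB or mmCIF file with gemmi (first model used downstream)."""
    if gemmi is None:  # pragma: no cover
        raise ImportError("gemmi is required for structure I/O")
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def extract_chain(structure, chain_id: str) -> ChainModel:
    """Build a :class:`ChainModel` from the first model of a gemmi structure.

    Alternate locations are resolved to the highest-occupancy conformer.
    Waters and metal ions from any chain are collected (ion sites often sit
    in their own het chains in deposited files).
    """
    model = structure[0]
    cm = ChainModel(chain_id=chain_id)
    for chain in model:
        for res in chain:
            is_water = res.name in ("HOH", "WAT", "DOD")
            is_ion = len(res) == 1 and res[0].element.is_metal
            if chain.name == chain_id and not is_water and not is_ion:
                r = Residue(seqid=res.seqid.num, name=res.name)
                best_occ: dict[str, float] = {}
                for atom in res:
                    occ = atom.occ
                    if atom.name not in r.atoms or occ > best_occ.get(atom.name, -1):
                        r.atoms[atom.name] = np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        )
                        r.elements[atom.name] = atom.element.name
                        best_occ[atom.name] = occ
                if r.atoms:
                    cm.residues.append(r)
            elif is_water:
                for atom in res:
                    if atom.element.name == "O":
                        cm.waters.append(
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                        )
            elif is_ion:
                atom = res[0]
                cm.ions[res.seqid.num] = (
                    atom.element.name.upper(),
                    np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
    cm.residues.sort(key=lambda r: r.seqid)
    return cm


# ---------------------------------------------------------------------------
# torsions


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass(frozen=True)
class TorsionRecord:
    """Backbone phi/psi for one residue; ``None`` marks an undefined angle."""

    chain_id: str
    seqid: int
    name: str
    phi: Optional[float]
    psi: Optional[float]


def compute_backbone_torsions(chain: ChainModel) -> list[TorsionRecord]:
    """Compute phi/psi for every residue of a chain.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Chain-terminal residues, residues flanking a chain break (C-N distance
    above 2.5 A) and residues with missing backbone atoms get ``None`` for
    the affected angle.
    """
    res = chain.residues
    out: list[TorsionRecord] = []
    for i, r in enumerate(res):
        phi = psi = None
        if r.has_backbone():
            if i > 0:
                p = res[i - 1]
                if "C" in p.atoms and _bonded(p.atoms["C"], r.atoms["N"]):
                    phi = dihedral(p.atoms["C"], r.atoms["N"], r.atoms["CA"], r.atoms["C"])
            if i + 1 < len(res):
                nxt = res[i + 1]
                if "N" in nxt.atoms and _bonded(r.atoms["C"], nxt.atoms["N"]):
                    psi = dihedral(r.atoms["N"], r.atoms["CA"], r.atoms["C"], nxt.atoms["N"])
        else:
            logger.warning(
                "residue %s%d %s missing backbone atoms; torsions undefined",
                chain.chain_id, r.seqid, r.name,
            )
        out.append(TorsionRecord(chain.chain_id, r.seqid, r.name, phi, psi))
    return out


def _bonded(c_coord, n_coord) -> bool:
    return float(np.linalg.norm(np.asarray(c_coord) - np.asarray(n_coord))) <= PEPTIDE_BOND_MAX


# ---------------------------------------------------------------------------
# beta-turn classification


@dataclass(frozen=True)
class TurnTypeDefinition:
    """Canonical (phi2, psi2, phi3, psi3) of a beta-turn type with tolerances.

    The matching convention is the standard one for turn assignment: each
    of the four angles must lie within ``tolerance`` of canonical, except
    that a single angle may deviate by up to ``relaxed_tolerance``.
    """

    name: str
    canonical: tuple[float, float, float, float]
    tolerance: float = 30.0
    relaxed_tolerance: float = 45.0


#: canonical turn-type library (type I and II as classically defined; the
#: primed, VIa1/VIb and VIII types complete the standard set)
TURN_TYPES: tuple[TurnTypeDefinition, ...] = (
    TurnTypeDefinition("I", (-60.0, -30.0, -90.0, 0.0)),
    TurnTypeDefinition("I'", (60.0, 30.0, 90.0, 0.0)),
    TurnTypeDefinition("II", (-60.0, 120.0, 90.0, 0.0)),
    TurnTypeDefinition("II'", (60.0, -120.0, -90.0, 0.0)),
    TurnTypeDefinition("VIa1", (-60.0, 120.0, -90.0, 0.0)),
    TurnTypeDefinition("VIb", (-135.0, 135.0, -75.0, 160.0)),
    TurnTypeDefinition("VIII", (-60.0, -30.0, -120.0, 120.0)),
)


def circular_delta(a: float, b: float) -> float:
    """Absolute circular difference of two angles in degrees, in [0, 180]."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class TurnAssignment:
    """Classification of one four-residue window."""

    seqids: tuple[int, ...]
    strict_type: Optional[str]
    nearest_type: str
    angular_distance: float
    is_turn: Optional[bool]
    has_1_4_hbond: Optional[bool]


def classify_beta_turn(
    angles: tuple[float, float, float, float],
    definitions: Sequence[TurnTypeDefinition] = TURN_TYPES,
    ca_coords: Optional[np.ndarray] = None,
    o1: Optional[np.ndarray] = None,
    n4: Optional[np.ndarray] = None,
    seqids: tuple[int, ...] = (),
    hbond_max: float = 3.5,
    ca_max: float = 7.0,
) -> TurnAssignment:
    """Classify a four-residue window from (phi2, psi2, phi3, psi3).

    ``strict_type`` is the definition matched within tolerance (all four
    angles within +/-30 deg, one of them allowed up to +/-45 deg); when
    several definitions match, the one with the smallest maximal deviation
    wins.  ``nearest_type`` minimizes the maximal circular deviation with
    no tolerance gate and is reported alongside, so that near-misses
    ("non-standard turn, more typical of type II") stay representable.
    ``is_turn`` applies the CA1-CA4 <= 7 A chain-reversal criterion and
    ``has_1_4_hbond`` the O(1)...N(4) <= 3.5 A criterion when coordinates
    are supplied.
    """
    if any(a is None for a in angles):
        raise ValueError(f"undefined torsion in window {seqids or angles}")
    devs = {}
    for d in definitions:
        deltas = [circular_delta(a, c) for a, c in zip(angles, d.canonical)]
        devs[d.name] = (max(deltas), deltas, d)
    nearest = min(devs, key=lambda k: devs[k][0])
    strict = None
    strict_dev = None
    for name, (mx, deltas, d) in devs.items():
        over = [x for x in deltas if x > d.tolerance]
        if not over or (len(over) == 1 and over[0] <= d.relaxed_tolerance):
            if strict is None or mx < strict_dev:
                strict, strict_dev = name, mx
    if strict is not None:
        nearest = strict
    is_turn = None
    if ca_coords is not None:
        ca_coords = np.asarray(ca_coords)
        is_turn = bool(np.linalg.norm(ca_coords[0] - ca_coords[3]) <= ca_max)
    hbond = None
    if o1 is not None and n4 is not None:
        hbond = bool(np.linalg.norm(np.asarray(o1) - np.asarray(n4)) <= hbond_max)
    return TurnAssignment(
        seqids=tuple(seqids),
        strict_type=strict,
        nearest_type=nearest,
        angular_distance=devs[nearest][0],
        is_turn=is_turn,
        has_1_4_hbond=hbond,
    )


def classify_window_from_chain(
    chain: ChainModel,
    torsions: Sequence[TorsionRecord],
    first_seqid: int,
    definitions: Sequence[TurnTypeDefinition] = TURN_TYPES,
) -> TurnAssignment:
    """Classify the four-residue window starting at ``first_seqid``."""
    by_id = chain.by_seqid()
    tors = {t.seqid: t for t in torsions}
    ids = [first_seqid + k for k in range(4)]
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ValueError(f"window residues missing from chain: {missing}")
    t2, t3 = tors[ids[1]], tors[ids[2]]
    if t2.phi is None or t2.psi is None or t3.phi is None or t3.psi is None:
        raise ValueError(f"undefined torsions in window {ids}")
    cas = [by_id[i].atoms.get("CA") for i in ids]
    ca_coords = np.array(cas) if all(c is not None for c in cas) else None
    return classify_beta_turn(
        (t2.phi, t2.psi, t3.phi, t3.psi),
        definitions=definitions,
        ca_coords=ca_coords,
        o1=by_id[ids[0]].atoms.get("O"),
        n4=by_id[ids[3]].atoms.get("N"),
        seqids=tuple(ids),
    )


# ---------------------------------------------------------------------------
# blade annotation sidecar


SEGMENT_ELEMENTS = (
    [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)] + ["C1", "C2"]
)
ANNOTATION_ELEMENTS = set(
    [f"strand{i}" for i in range(1, 5)]
    + SEGMENT_ELEMENTS
    + ["caloop12", "caloop34", "ca_ion"]
)


@dataclass
class BladeAnnotation:
    """Residue-level annotation of one blade (author numbering).

    ``segments`` maps the motif positions (A0-A4, B0-B4, C1, C2) to single
    residue numbers; ``strands`` maps strand index 1-4 to residue ranges;
    the two calcium loops (between strands 1,2 and strands 3,4) are ranges;
    ``ca_ion`` is the het seqid of a bound calcium, if any.
    """

    chain_id: str
    blade: int
    strands: dict[int, tuple[int, int]] = field(default_factory=dict)
    segments: dict[str, int] = field(default_factory=dict)
    ca_loop12: Optional[tuple[int, int]] = None
    ca_loop34: Optional[tuple[int, int]] = None
    ca_ion: Optional[int] = None

    def segment_residues(self, segment: str) -> list[int]:
        """All annotated residue numbers belonging to segment 'A', 'B' or 'C'."""
        return sorted(
            v for k, v in self.segments.items() if k.startswith(segment)
        )

    @property
    def span(self) -> tuple[int, int]:
        ids: list[int] = []
        for lo, hi in self.strands.values():
            ids += [lo, hi]
        ids += list(self.segments.values())
        for rng in (self.ca_loop12, self.ca_loop34):
            if rng:
                ids += [rng[0], rng[1]]
        if not ids:
            raise ValueError("empty blade annotation")
        return (min(ids), max(ids))

    def validate(self) -> None:
        missing = [
            e for e in ("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4")
            if e not in self.segments
        ]
        if missing:
            raise ValueError(
                f"blade {self.blade} annotation incomplete: missing {missing}"
            )


def read_annotation(path) -> dict[str, dict[int, BladeAnnotation]]:
    """Read a blade annotation sidecar TSV.

    Columns: ``chain  blade  element  start  end`` with element one of
    strand1..strand4, A0..A4, B0..B4, C1, C2, caloop12, caloop34, ca_ion.
    Returns ``{chain_id: {blade_number: BladeAnnotation}}``.
    """
    out: dict[str, dict[int, BladeAnnotation]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0].lower() == "chain":
                continue
            if len(parts) < 5:
                raise ValueError(f"annotation line {line_no}: expected 5 columns")
            chain_id, blade_s, element, start_s, end_s = parts[:5]
            if element not in ANNOTATION_ELEMENTS:
                raise ValueError(
                    f"annotation line {line_no}: unknown element {element!r}"
                )
            blade = int(blade_s)
            start, end = int(start_s), int(end_s)
            ann = out.setdefault(chain_id, {}).setdefault(
                blade, BladeAnnotation(chain_id=chain_id, blade=blade)
            )
            if element.startswith("strand"):
                ann.strands[int(element[-1])] = (start, end)
            elif element == "caloop12":
                ann.ca_loop12 = (start, end)
            elif element == "caloop34":
                ann.ca_loop34 = (start, end)
            elif element == "ca_ion":
                ann.ca_ion = start
            else:
                ann.segments[element] = start
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds


@dataclass(frozen=True)
class HBond:
    """A main-chain N-H...O=C hydrogen bond between annotated residues."""

    donor_seqid: int
    acceptor_seqid: int
    distance: float
    donor_angle: Optional[float]
    intra_turn: bool
    pair_label: str  # "A-B", "A-C", "B-C" or "within-A" etc.


@dataclass(frozen=True)
class HBondCriteria:
    max_no_distance: float = 3.5  # N...O, Angstrom
    min_donor_angle: float = 120.0  # N-H...O, degrees, when H inferable
    min_sequence_separation: int = 2  # |i-j| below this is skipped


def _amide_hydrogen(prev_c, n, ca) -> Optional[np.ndarray]:
    """Infer the backbone amide H position from C(i-1), N(i), CA(i)."""
    if prev_c is None:
        return None
    n = np.asarray(n)
    u = n - np.asarray(prev_c)
    v = n - np.asarray(ca)
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = u + v
    norm = np.linalg.norm(d)
    if norm < 1e-8:
        return None
    return n + d / norm * 1.01


def detect_mainchain_hbonds(
    chain: ChainModel,
    annotation: BladeAnnotation,
    criteria: HBondCriteria | None = None,
) -> list[HBond]:
    """Detect main-chain N->O hydrogen bonds among segments A, B and C.

    All donor(N)/acceptor(O) pairs over the annotated segment residues are
    tested against N...O <= 3.5 A; when the amide hydrogen is inferable
    (previous residue present) the N-H...O angle must be >= 120 deg.
    Sequence neighbours (|i-j| < 2) are skipped.  Each bond is labelled by
    its segment pair, and as ``intra_turn`` when it is the O(1)...N(4) bond
    of the segment A or segment B turn window.
    """
    criteria = criteria or HBondCriteria()
    by_id = chain.by_seqid()
    seg_of: dict[int, str] = {}
    for seg in ("A", "B", "C"):
        for sid in annotation.segment_residues(seg):
            seg_of[sid] = seg
    residues = sorted(seg_of)
    turn_pairs = set()
    for seg, base in (("A", "A1"), ("B", "B1")):
        ids = [annotation.segments.get(f"{seg}{k}") for k in (1, 2, 3, 4)]
        if all(i is not None for i in ids):
            turn_pairs.add((ids[3], ids[0]))  # donor N(4) -> acceptor O(1)
    bonds: list[HBond] = []
    for di in residues:
        donor = by_id.get(di)
        if donor is None or "N" not in donor.atoms:
            logger.warning("donor residue %d missing N atom; skipped", di)
            continue
        prev = by_id.get(di - 1)
        h = _amide_hydrogen(
            prev.atoms.get("C") if prev else None,
            donor.atoms["N"],
            donor.atoms.get("CA", donor.atoms["N"] + np.array([1.0, 0, 0])),
        )
        for ai in residues:
            if abs(di - ai) < criteria.min_sequence_separation:
                continue
            acceptor = by_id.get(ai)
            if acceptor is None or "O" not in acceptor.atoms:
                continue
            dist = float(np.linalg.norm(donor.atoms["N"] - acceptor.atoms["O"]))
            if dist > criteria.max_no_distance:
                continue
            angle = None
            if h is not None:
                v1 = donor.atoms["N"] - h
                v2 = acceptor.atoms["O"] - h
                cosang = float(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle < criteria.min_donor_angle:
                    continue
            sa, sb = seg_of[di], seg_of[ai]
            label = f"within-{sa}" if sa == sb else "-".join(sorted((sa, sb)))
            bonds.append(
                HBond(
                    donor_seqid=di,
                    acceptor_seqid=ai,
                    distance=dist,
                    donor_angle=angle,
                    intra_turn=(di, ai) in turn_pairs,
                    pair_label=label,
                )
            )
    return bonds


def count_intersegment_hbonds(bonds: Sequence[HBond]) -> int:
    return sum(1 for b in bonds if "-" in b.pair_label and not b.pair_label.startswith("within"))


# ---------------------------------------------------------------------------
# calcium-site geometry


@dataclass
class CaSiteReport:
    """Coordination shell of one blade's calcium site."""

    ion_seqid: Optional[int]
    site_present: bool
    ligands: list[tuple[str, float]] = field(default_factory=list)
    n_ligands: int = 0
    bridging_water: bool = False
    loop34_glycine_contact: bool = False


@dataclass(frozen=True)
class CaSiteCriteria:
    coordination_max: float = 3.0  # Ca...O, Angstrom
    water_bridge_max: float = 3.2  # Ca...water O
    hbond_max: float = 3.5  # water O ... main-chain O/N of the 3,4-loop Gly


def verify_ca_site(
    chain: ChainModel,
    annotation: BladeAnnotation,
    criteria: CaSiteCriteria | None = None,
) -> CaSiteReport:
    """Check the coordination geometry of an annotated calcium site.

    The ligand shell collects every oxygen atom (protein or water) within
    the coordination cutoff of the ion.  A bridging water must lie within
    the water-bridge cutoff of the ion *and* within hydrogen-bond distance
    of a main-chain O or N of a glycine in the 3,4-loop — the structural
    hallmark that couples the two calcium loops of a blade.
    """
    criteria = criteria or CaSiteCriteria()
    if annotation.ca_ion is None or annotation.ca_ion not in chain.ions:
        return CaSiteReport(ion_seqid=annotation.ca_ion, site_present=False)
    element, ion = chain.ions[annotation.ca_ion]
    ligands: list[tuple[str, float]] = []
    for res in chain.residues:
        for aname, coord in res.atoms.items():
            if res.elements.get(aname) != "O":
                continue
            d = float(np.linalg.norm(coord - ion))
            if d <= criteria.coordination_max:
                ligands.append((f"{res.seqid}:{aname}", d))
    for wi, w in enumerate(chain.waters):
        d = float(np.linalg.norm(w - ion))
        if d <= criteria.coordination_max:
            ligands.append((f"HOH{wi}:O", d))
    ligands.sort(key=lambda t: t[1])
    # bridging water / 3,4-loop glycine contact
    bridging = False
    gly_contact = False
    gly_atoms: list[np.ndarray] = []
    if annotation.ca_loop34:
        lo, hi = annotation.ca_loop34
        for res in chain.residues:
            if lo <= res.seqid <= hi and res.name in ("GLY",):
                for aname in ("O", "N"):
                    if aname in res.atoms:
                        gly_atoms.append(res.atoms[aname])
    for w in chain.waters:
        if float(np.linalg.norm(w - ion)) > criteria.water_bridge_max:
            continue
        for g in gly_atoms:
            if float(np.linalg.norm(w - g)) <= criteria.hbond_max:
                bridging = True
                gly_contact = True
                break
        if bridging:
            break
    return CaSiteReport(
        ion_seqid=annotation.ca_ion,
        site_present=bool(ligands),
        ligands=ligands,
        n_ligands=len(ligands),
        bridging_water=bridging,
        loop34_glycine_contact=gly_contact,
    )


# ---------------------------------------------------------------------------
# blade / domain verdicts


@dataclass
class BladeVerdict:
    """Pass/fail ledger of characteristics 1-4 for one blade."""

    blade: int
    char1_cage: bool
    char2_turns: bool
    char3_hbond_network: bool
    char4_ca_motif: bool
    turn_a: Optional[TurnAssignment] = None
    turn_b: Optional[TurnAssignment] = None
    n_intersegment_hbonds: int = 0
    ca_site: Optional[CaSiteReport] = None

    @property
    def all_pass(self) -> bool:
        return (
            self.char1_cage
            and self.char2_turns
            and self.char3_hbond_network
            and self.char4_ca_motif
        )


@dataclass(frozen=True)
class VerifySpecs:
    cage_spec: CagePatternSpec = CagePatternSpec()
    ca_spec: CaMotifSpec = CaMotifSpec()
    hbond: HBondCriteria = HBondCriteria()
    ca_site: CaSiteCriteria = CaSiteCriteria()
    min_intersegment_hbonds: int = 5
    turn_mode: str = "strict"  # "strict" | "nearest"
    min_ca_ligands: int = 4


def _turn_matches(assignment: TurnAssignment, wanted: str, mode: str) -> bool:
    if mode == "strict":
        return assignment.strict_type == wanted
    return assignment.nearest_type == wanted


def verify_blade(
    chain: ChainModel,
    annotation: BladeAnnotation,
    sequence: Optional[str] = None,
    specs: VerifySpecs | None = None,
    torsions: Optional[Sequence[TorsionRecord]] = None,
) -> BladeVerdict:
    """Evaluate characteristics 1-4 on one annotated blade.

    ``sequence`` is the chain's one-letter sequence indexed by author
    residue number (1-based); when omitted it is derived from the chain
    model.  In ``strict`` turn mode characteristic 2 requires a strict
    type II assignment in segment A and strict type I in segment B; in
    ``nearest`` mode the nearest-type fallback is accepted.
    """
    specs = specs or VerifySpecs()
    annotation.validate()
    if torsions is None:
        torsions = compute_backbone_torsions(chain)
    if sequence is None:
        seq_by_id = {r.seqid: _three_to_one(r.name) for r in chain.residues}
        max_id = max(seq_by_id)
        sequence = "".join(seq_by_id.get(i, "X") for i in range(1, max_id + 1))
    lo, hi = annotation.span
    lo = max(1, lo)
    blade_seq = sequence[lo - 1 : hi]
    char1 = bool(scan_cage(blade_seq, specs.cage_spec))
    turn_a = classify_window_from_chain(chain, torsions, annotation.segments["A1"])
    turn_b = classify_window_from_chain(chain, torsions, annotation.segments["B1"])
    char2 = _turn_matches(turn_a, "II", specs.turn_mode) and _turn_matches(
        turn_b, "I", specs.turn_mode
    )
    bonds = detect_mainchain_hbonds(chain, annotation, specs.hbond)
    n_inter = count_intersegment_hbonds(bonds)
    char3 = n_inter >= specs.min_intersegment_hbonds
    ca_seq = bool(scan_ca(blade_seq, specs.ca_spec))
    ca_report = None
    if annotation.ca_ion is not None:
        ca_report = verify_ca_site(chain, annotation, specs.ca_site)
        char4 = ca_seq and ca_report.site_present and (
            ca_report.n_ligands >= specs.min_ca_ligands
        )
    else:
        char4 = ca_seq
    return BladeVerdict(
        blade=annotation.blade,
        char1_cage=char1,
        char2_turns=char2,
        char3_hbond_network=char3,
        char4_ca_motif=char4,
        turn_a=turn_a,
        turn_b=turn_b,
        n_intersegment_hbonds=n_inter,
        ca_site=ca_report,
    )


@dataclass
class DomainVerdict:
    """Aggregate verdict over the seven blades plus characteristic 5."""

    blades: list[BladeVerdict]
    characteristic5: bool

    def __post_init__(self):
        if len(self.blades) != 7:
            raise ValueError("a propeller domain verdict needs exactly 7 blades")


def _strand_pairing(
    cas_a: Sequence[np.ndarray],
    cas_b: Sequence[np.ndarray],
    max_dist: float = 5.5,
    min_run: int = 3,
) -> bool:
    """True when the two CA traces pair over >= min_run consecutive residues.

    Both parallel and antiparallel register shifts are scanned.
    """
    a = np.asarray(cas_a)
    if len(a) < min_run:
        return False
    for b in (np.asarray(cas_b), np.asarray(cas_b)[::-1]):
        if len(b) < min_run:
            continue
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2) <= max_dist
        n, m = d.shape
        for off in range(-(n - 1), m):
            run = 0
            for i in range(n):
                j = i + off
                if 0 <= j < m and d[i, j]:
                    run += 1
                    if run >= min_run:
                        return True
                else:
                    run = 0
    return False


def verify_domain(
    chain: ChainModel,
    annotations: Sequence[BladeAnnotation],
    sequence: Optional[str] = None,
    specs: VerifySpecs | None = None,
    n_terminal_window: int = 12,
) -> DomainVerdict:
    """Evaluate all five characteristics on a seven-blade propeller domain.

    Characteristic 5 holds when a strand-length backbone segment N-terminal
    to blade 1 pairs (CA-CA <= 5.5 A over >= 3 consecutive residue pairs)
    with strand 3 of blade 7, i.e. the propeller ring is closed by a
    non-sequential fourth strand in the last blade.
    """
    if len(annotations) != 7:
        raise ValueError(f"expected 7 blade annotations, got {len(annotations)}")
    specs = specs or VerifySpecs()
    torsions = compute_backbone_torsions(chain)
    verdicts = [
        verify_blade(chain, ann, sequence, specs, torsions) for ann in annotations
    ]
    char5 = False
    blade1_start = annotations[0].span[0]
    strand3 = annotations[6].strands.get(3)
    if strand3:
        by_id = chain.by_seqid()
        pre = [
            by_id[i].atoms["CA"]
            for i in range(blade1_start - n_terminal_window, blade1_start)
            if i in by_id and "CA" in by_id[i].atoms
        ]
        s3 = [
            by_id[i].atoms["CA"]
            for i in range(strand3[0], strand3[1] + 1)
            if i in by_id and "CA" in by_id[i].atoms
        ]
        if len(pre) >= 3 and len(s3) >= 3:
            char5 = _strand_pairing(pre, s3)
    return DomainVerdict(blades=verdicts, characteristic5=char5)
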