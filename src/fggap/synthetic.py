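"""Labeled synthetic inputs with the statistical structure the scanners assume.

Sequence side: proteins built from ~60-residue blade repeats, each carrying
the Cage consensus (gaps drawn uniformly from their ranges) and, by
default, a DxDxDG calcium loop in every blade — the architecture seen in
the bacterial seven-repeat proteins, where the calcium signature is present
in all seven blades (human integrins carry it in only three or four).
Decoys (shuffled positives), partial-repeat proteins and tandem
double-domain proteins probe each funnel stage separately.

Structure side: backbones built from prescribed phi/psi with ideal bond
geometry (N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A, omega = 180 deg), plus
small constructed calcium sites and blade-like assemblies for exercising
the geometric validators.  All constructed coordinates are synthetic and
labelled as such; no full propeller structures are generated.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .patterns import STANDARD_AA, CagePatternSpec
from .structure import BladeAnnotation, ChainModel, Residue

ALL_AA = sorted(STANDARD_AA)
#: letters that can seed spurious Cage/Ca anchors
ANCHOR_LETTERS = set("FWYGP")
CLEAN_AA = sorted(STANDARD_AA - ANCHOR_LETTERS - set("DN"))
#: replacement letter that matches no anchor and no Ca position
NULL_LETTER = "L"


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the sequence generator.

    ``fidelity`` is the probability that each fixed anchor letter of the
    Cage motif is planted intact (an unfaithful anchor is replaced by a
    letter that cannot match it); ``ca_motif_rate`` is the fraction of
    blades given a DxDxDG loop (default 1.0, the bacterial architecture).
    ``clean_background`` restricts background letters to residues that can
    never seed an anchor — the configuration used for exact-recovery
    checks.
    """

    n_blades: int = 7
    blade_length: tuple[int, int] = (50, 70)
    fidelity: float = 1.0
    ca_motif_rate: float = 1.0
    linker_length: tuple[int, int] = (5, 40)
    tandem_linker: tuple[int, int] = (150, 250)
    terminal_length: tuple[int, int] = (5, 30)
    clean_background: bool = False
    cage_spec: CagePatternSpec = field(default_factory=CagePatternSpec)

    def __post_init__(self):
        if not (0.0 <= self.fidelity <= 1.0 and 0.0 <= self.ca_motif_rate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.blade_length[0] < self.cage_spec.min_length:
            raise ValueError(
                f"blade length lower bound {self.blade_length[0]} is below the "
                f"Cage minimum {self.cage_spec.min_length}"
            )

    @property
    def background(self) -> list[str]:
        return CLEAN_AA if self.clean_background else ALL_AA


@dataclass
class PlantedBlade:
    """Planted truth for one blade, 1-based coordinates within the protein."""

    span: tuple[int, int]
    cage_anchors: tuple[int, ...]
    cage_span: tuple[int, int]
    ca_span: Optional[tuple[int, int]]
    intact: bool  # all cage anchors planted faithfully

    def shifted(self, off: int) -> "PlantedBlade":
        return PlantedBlade(
            span=(self.span[0] + off, self.span[1] + off),
            cage_anchors=tuple(a + off for a in self.cage_anchors),
            cage_span=(self.cage_span[0] + off, self.cage_span[1] + off),
            ca_span=(
                (self.ca_span[0] + off, self.ca_span[1] + off)
                if self.ca_span
                else None
            ),
            intact=self.intact,
        )


@dataclass
class LabeledRecord:
    """A generated protein with its ground-truth label and planted spans."""

    id: str
    sequence: str
    label: str  # positive_single | positive_tandem | partial | decoy
    blades: list[PlantedBlade] = field(default_factory=list)

    @property
    def n_intact(self) -> int:
        return sum(1 for b in self.blades if b.intact)


def _bg(rng: np.random.Generator, params: GeneratorParams, n: int) -> list[str]:
    bg = params.background
    return [bg[i] for i in rng.integers(0, len(bg), size=n)]


def _miss_letter(rng: np.random.Generator, forbidden: set[str]) -> str:
    pool = [a for a in CLEAN_AA if a not in forbidden]
    return pool[rng.integers(0, len(pool))]


def generate_blade(
    params: GeneratorParams, rng: np.random.Generator
) -> tuple[str, PlantedBlade]:
    """Generate one blade sequence with a planted Cage (and optional Ca loop).

    The Cage block starts at the first blade residue (mirroring strand 1
    opening the blade); gap widths are drawn uniformly from the pattern
    ranges.  At fidelity p each anchor letter is planted intact with
    probability p and otherwise replaced by a letter that cannot match the
    anchor.  The DxDxDG hexamer is placed after the Cage block when room
    remains, else inside the first gap — never on an anchor position.
    Returns the blade string and its planted-truth map (1-based, blade
    coordinates).
    """
    spec = params.cage_spec
    lo, hi = params.blade_length
    for _ in range(64):
        blade_len = int(rng.integers(lo, hi + 1))
        g1 = int(rng.integers(spec.gap1_range[0], spec.gap1_range[1] + 1))
        g2 = int(rng.integers(spec.gap2_range[0], spec.gap2_range[1] + 1))
        tail = int(rng.integers(spec.tail_range[0], spec.tail_range[1] + 1))
        cage_len = 4 + g1 + 1 + g2 + 1 + tail
        if cage_len <= blade_len:
            break
    else:
        raise RuntimeError("could not draw a feasible blade length / gap combination")
    letters = _bg(rng, params, blade_len)
    aromatics = sorted(spec.aromatic_set)
    p_pos = 4 + g1
    g_pos = p_pos + 1 + g2
    anchors = [0, 1, 2, 3, p_pos, g_pos]
    wanted = [set(aromatics), set(aromatics), {"G"}, set(aromatics), {"P"}, {"G"}]
    intact = True
    for pos, want in zip(anchors, wanted):
        if rng.random() < params.fidelity:
            choices = sorted(want)
            letters[pos] = choices[rng.integers(0, len(choices))]
        else:
            letters[pos] = _miss_letter(rng, want)
            intact = False
    cage_end = g_pos + tail  # 0-based inclusive
    ca_span = None
    if rng.random() < params.ca_motif_rate:
        room_after = blade_len - (cage_end + 1)
        if room_after >= 6:
            ca_start = cage_end + 1 + int(rng.integers(0, room_after - 6 + 1))
        else:
            # inside gap1 (positions 4 .. p_pos-1, width g1 >= 13)
            ca_start = 4 + int(rng.integers(0, g1 - 6 + 1))
        for k, letter in enumerate("D_D_DG"):
            if letter != "_":
                letters[ca_start + k] = letter
        ca_span = (ca_start + 1, ca_start + 6)
    planted = PlantedBlade(
        span=(1, blade_len),
        cage_anchors=tuple(a + 1 for a in anchors),
        cage_span=(1, cage_end + 1),
        ca_span=ca_span,
        intact=intact,
    )
    return "".join(letters), planted


def generate_protein(
    params: GeneratorParams,
    label: str,
    rng: np.random.Generator,
    record_id: str = "synthetic",
    k: Optional[int] = None,
) -> LabeledRecord:
    """Generate a labelled protein.

    ``positive_single``: seven blades joined by short linkers;
    ``positive_tandem``: two seven-blade groups separated by a long linker;
    ``partial``: ``k`` (< 7) blades; ``decoy``: a shuffled positive (same
    composition, no planted structure).  An N-terminal extension and a
    C-terminal tail of background residues flank the repeats.
    """
    if label == "partial":
        n = k if k is not None else 3
        if not (1 <= n < params.n_blades):
            raise ValueError("partial requires 1 <= k < n_blades")
        groups = [n]
    elif label == "positive_single":
        groups = [params.n_blades]
    elif label == "positive_tandem":
        groups = [params.n_blades, params.n_blades]
    elif label == "decoy":
        base = generate_protein(params, "positive_single", rng, record_id)
        letters = list(base.sequence)
        perm = rng.permutation(len(letters))
        return LabeledRecord(
            id=record_id,
            sequence="".join(letters[i] for i in perm),
            label="decoy",
            blades=[],
        )
    else:
        raise ValueError(f"unknown label {label!r}")
    pieces: list[str] = []
    blades: list[PlantedBlade] = []
    pos = 0
    nterm = int(rng.integers(*_incl(params.terminal_length)))
    pieces.append("".join(_bg(rng, params, nterm)))
    pos += nterm
    for gi, group in enumerate(groups):
        if gi > 0:
            link = int(rng.integers(*_incl(params.tandem_linker)))
            pieces.append("".join(_bg(rng, params, link)))
            pos += link
        for bi in range(group):
            if bi > 0:
                link = int(rng.integers(*_incl(params.linker_length)))
                pieces.append("".join(_bg(rng, params, link)))
                pos += link
            seq, planted = generate_blade(params, rng)
            pieces.append(seq)
            blades.append(planted.shifted(pos))
            pos += len(seq)
    cterm = int(rng.integers(*_incl(params.terminal_length)))
    pieces.append("".join(_bg(rng, params, cterm)))
    return LabeledRecord(
        id=record_id, sequence="".join(pieces), label=label, blades=blades
    )


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return (rng_pair[0], rng_pair[1] + 1)


def generate_labeled_set(
    n_positive: int = 10,
    n_partial: int = 20,
    n_decoy: int = 70,
    params: GeneratorParams | None = None,
    seed: int = 0,
    partial_k: int = 3,
    n_tandem: int = 0,
) -> list[LabeledRecord]:
    """Generate the standard benchmark mix of positives, partials and decoys."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    records: list[LabeledRecord] = []
    for i in range(n_positive):
        records.append(generate_protein(params, "positive_single", rng, f"pos_{i}"))
    for i in range(n_tandem):
        records.append(generate_protein(params, "positive_tandem", rng, f"tan_{i}"))
    for i in range(n_partial):
        records.append(
            generate_protein(params, "partial", rng, f"part_{i}", k=partial_k)
        )
    for i in range(n_decoy):
        records.append(generate_protein(params, "decoy", rng, f"dec_{i}"))
    return records


def ablate_motif(
    record: LabeledRecord, element: str, blade_index: int = 0
) -> LabeledRecord:
    """Replace a planted motif element by non-matching letters.

    ``element`` is ``cage_anchor`` (all six Cage anchors of one blade),
    ``ca_loop`` (the DxDxDG hexamer of one blade) or ``blade`` (the whole
    blade span).  The label is downgraded to match the remaining number of
    intact blades.
    """
    if element not in ("cage_anchor", "ca_loop", "blade"):
        raise ValueError(f"unknown ablation element {element!r}")
    if not (0 <= blade_index < len(record.blades)):
        raise ValueError(f"record has no blade {blade_index}")
    letters = list(record.sequence)
    blades = list(record.blades)
    target = blades[blade_index]
    if element == "cage_anchor":
        for a in target.cage_anchors:
            letters[a - 1] = NULL_LETTER
        blades[blade_index] = replace(target, intact=False)
    elif element == "ca_loop":
        if target.ca_span is None:
            raise ValueError(f"blade {blade_index} has no planted ca loop")
        for i in range(target.ca_span[0], target.ca_span[1] + 1):
            letters[i - 1] = NULL_LETTER
        blades[blade_index] = replace(target, ca_span=None)
    else:
        for i in range(target.span[0], target.span[1] + 1):
            letters[i - 1] = NULL_LETTER
        blades[blade_index] = replace(target, intact=False, ca_span=None)
    n_intact = sum(1 for b in blades if b.intact)
    if n_intact >= 14:
        label = "positive_tandem"
    elif n_intact >= 7:
        label = "positive_single"
    elif n_intact >= 1:
        label = "partial"
    else:
        label = "decoy"
    return LabeledRecord(
        id=record.id, sequence="".join(letters), label=label, blades=blades
    )


# ---------------------------------------------------------------------------
# ideal-geometry backbone construction

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates.

    ``angle`` is the b-c-d bond angle and ``torsion`` the a-b-c-d dihedral,
    both in degrees (the natural-extension reference frame construction).
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: Sequence[tuple[float, float]],
    chain_id: str = "A",
    start_seqid: int = 1,
    residue_names: Optional[Sequence[str]] = None,
    omega: float = 180.0,
) -> ChainModel:
    """Build an N/CA/C/O backbone from a (phi, psi) list with ideal geometry.

    phi of the first residue and psi of the last shape only the terminal
    oxygen; recomputing torsions on the result reproduces the interior
    angles to ~1e-5 degrees.
    """
    n_res = len(phi_psi)
    if residue_names is None:
        residue_names = ["ALA"] * n_res
    coords: list[dict[str, np.ndarray]] = []
    # seed the first residue in a canonical frame
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[i - 1]
        psi_prev = phi_psi[i - 1][1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, omega)
        c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next N (torsion psi - 180)
    for i in range(n_res):
        psi = phi_psi[i][1]
        coords[i]["O"] = place_atom(
            coords[i]["N"], coords[i]["CA"], coords[i]["C"],
            BOND_C_O, ANGLE_CA_C_O, psi - 180.0,
        )
    chain = ChainModel(chain_id=chain_id)
    for i, atoms in enumerate(coords):
        r = Residue(seqid=start_seqid + i, name=residue_names[i])
        for name, coord in atoms.items():
            r.atoms[name] = coord
            r.elements[name] = name[0]
        chain.residues.append(r)
    return chain


TURN_ANGLES = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 90.0, 0.0),
    "II'": (60.0, -120.0, -90.0, 0.0),
}


def generate_turn_coords(
    turn: str | tuple[float, float, float, float],
    chain_id: str = "A",
    start_seqid: int = 1,
) -> ChainModel:
    """Build a four-residue backbone realizing a beta-turn.

    ``turn`` is a canonical type name (I, I', II, II') or an explicit
    (phi2, psi2, phi3, psi3) tuple.  Flanking residues take extended-chain
    angles; residue 3 of a type II turn is named GLY, residue 2 of a type I
    turn PRO, matching the conserved composition.
    """
    if isinstance(turn, str):
        phi2, psi2, phi3, psi3 = TURN_ANGLES[turn]
        names = {
            "II": ["ALA", "ALA", "GLY", "ALA"],
            "I": ["ALA", "PRO", "ALA", "ALA"],
        }.get(turn, ["ALA"] * 4)
    else:
        phi2, psi2, phi3, psi3 = turn
        names = ["ALA"] * 4
    phi_psi = [(-120.0, 140.0), (phi2, psi2), (phi3, psi3), (-120.0, 140.0)]
    return build_backbone(phi_psi, chain_id, start_seqid, names)


def make_octahedral_ca_site(
    ligand_distance: float = 2.4,
    chain_id: str = "A",
) -> tuple[ChainModel, BladeAnnotation]:
    """Construct an idealized octahedral calcium site (synthetic fixture).

    Five protein oxygens and one water oxygen sit at the octahedron
    vertices; the water also hydrogen-bonds the main-chain of a glycine
    standing in for the 3,4-loop, so the bridging-water criterion holds.
    """
    chain = ChainModel(chain_id=chain_id)
    ion = np.zeros(3)
    vertices = [
        np.array(v) * ligand_distance
        for v in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, -1)]
    ]
    for i, v in enumerate(vertices):
        r = Residue(seqid=10 + i, name="ASP")
        r.atoms["OD1"] = v
        r.elements["OD1"] = "O"
        chain.residues.append(r)
    water = np.array([0.0, 0.0, ligand_distance])
    chain.waters.append(water)
    gly = Residue(seqid=40, name="GLY")
    gly.atoms["O"] = water + np.array([0.0, 2.8, 0.0])
    gly.elements["O"] = "O"
    gly.atoms["N"] = water + np.array([0.0, 2.8, 1.2])
    gly.elements["N"] = "N"
    chain.residues.append(gly)
    chain.ions[900] = ("CA", ion)
    ann = BladeAnnotation(
        chain_id=chain_id,
        blade=1,
        ca_loop12=(10, 14),
        ca_loop34=(40, 40),
        ca_ion=900,
    )
    return chain, ann


# ---------------------------------------------------------------------------
# synthetic blade / domain assemblies for the verdict checks


def _isolated_residue(seqid: int, name: str, n_at, o_at) -> Residue:
    r = Residue(seqid=seqid, name=name)
    r.atoms["N"] = np.asarray(n_at, dtype=float)
    r.elements["N"] = "N"
    r.atoms["O"] = np.asarray(o_at, dtype=float)
    r.elements["O"] = "O"
    return r


def make_synthetic_blade(
    seed: int = 0,
    offset: int = 0,
    chain_id: str = "A",
    separated: bool = False,
) -> tuple[ChainModel, BladeAnnotation, str]:
    """Assemble a synthetic blade satisfying characteristics 1-4.

    A type II turn window (segment A) and a type I turn window (segment B)
    are built with ideal geometry; the flanking segment residues (A0, B0,
    C1, C2) are free-floating and placed so that exactly five
    inter-segment N...O contacts exist at hydrogen-bond distance.  The
    accompanying sequence carries a planted Cage motif and DxDxDG loop.
    With ``separated=True`` the B/C parts are pushed 60 A away, destroying
    the network (characteristic 3 then fails).

    Returns (chain fragment, annotation, blade sequence); annotation
    residue numbers are 1-based positions into the sequence, shifted by
    ``offset``.
    """
    rng = np.random.default_rng(seed)
    params = GeneratorParams(clean_background=True, ca_motif_rate=1.0)
    seq, planted = generate_blade(params, rng)
    # choose annotation slots inside the blade (positions are synthetic:
    # the geometry does not come from the sequence)
    a1 = 10
    b1 = 20
    a_ids = [a1 + k for k in range(4)]  # A1..A4
    b_ids = [b1 + k for k in range(4)]  # B1..B4
    a0, b0, c1, c2 = 9, 19, 30, 31
    shift = np.array([60.0, 0.0, 0.0]) if separated else np.zeros(3)
    turn_a = build_backbone(
        [(-120, 140), (-60, 120), (90, 0), (-120, 140)],
        chain_id, a1, ["ALA", "ALA", "GLY", "ALA"],
    )
    turn_b = build_backbone(
        [(-120, 140), (-60, -30), (-90, 0), (-120, 140)],
        chain_id, b1, ["ALA", "PRO", "ALA", "ALA"],
    )
    # park the B turn near the A turn but out of contact range (> 6 A)
    for r in turn_b.residues:
        for k in r.atoms:
            r.atoms[k] = r.atoms[k] + np.array([0.0, 9.0, 0.0]) + shift
    chain = ChainModel(chain_id=chain_id)
    chain.residues.extend(turn_a.residues)
    chain.residues.extend(turn_b.residues)
    by_id = {r.seqid: r for r in chain.residues}
    far = np.array([200.0, 200.0, 200.0])
    cluster_a = np.mean(
        [by_id[i].atoms[k] for i in a_ids for k in ("N", "O")], axis=0
    )
    cluster_b = np.mean(
        [by_id[i].atoms[k] for i in b_ids for k in ("N", "O")], axis=0
    )

    def near(atom_coord, local_cluster, d=3.2):
        # approach the acceptor from outside its turn so only the intended
        # oxygen falls within hydrogen-bond distance
        o = np.asarray(atom_coord)
        out = o - local_cluster
        out = out / np.linalg.norm(out)
        return o + d * out

    # five inter-segment N...O contacts: A-B x2, A-C x2, B-C x1; all donors
    # are isolated residues (no preceding carbonyl), so the distance
    # criterion alone applies
    a0_n = near(by_id[b_ids[2]].atoms["O"], cluster_b)
    a0_res = _isolated_residue(a0, "ALA", a0_n, far)
    b0_res = _isolated_residue(
        b0, "ALA", near(by_id[a_ids[2]].atoms["O"], cluster_a), far + 5
    )
    c1_res = _isolated_residue(
        c1, "ALA", near(by_id[a_ids[0]].atoms["O"], cluster_a), far + 10
    )
    c2_o = a0_n + (a0_n - cluster_b) / np.linalg.norm(a0_n - cluster_b) * 3.2
    c2_res = _isolated_residue(
        c2, "ALA", near(by_id[b_ids[1]].atoms["O"], cluster_b), c2_o
    )
    for r in (a0_res, b0_res, c1_res, c2_res):
        if separated and r.seqid in (b0, c1, c2):
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + shift
        chain.residues.append(r)
    chain.residues.sort(key=lambda r: r.seqid)
    if offset:
        for r in chain.residues:
            r.seqid += offset
    ann = BladeAnnotation(
        chain_id=chain_id,
        blade=1,
        strands={1: (1 + offset, len(seq) + offset)},
        segments={
            "A0": a0 + offset,
            **{f"A{k+1}": a_ids[k] + offset for k in range(4)},
            "B0": b0 + offset,
            **{f"B{k+1}": b_ids[k] + offset for k in range(4)},
            "C1": c1 + offset,
            "C2": c2 + offset,
        },
    )
    return chain, ann, seq
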