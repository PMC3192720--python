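"""Torsion engine, turn classifier, H-bond network and calcium-site geometry."""

import math

import numpy as np
import pytest

from fggap.structure import (
    BladeAnnotation,
    CaSiteCriteria,
    HBondCriteria,
    TURN_TYPES,
    VerifySpecs,
    ChainModel,
    classify_beta_turn,
    classify_window_from_chain,
    compute_backbone_torsions,
    count_intersegment_hbonds,
    detect_mainchain_hbonds,
    dihedral,
    extract_chain,
    load_structure,
    read_annotation,
    verify_blade,
    verify_ca_site,
    verify_domain,
)
from fggap.synthetic import (
    build_backbone,
    generate_turn_coords,
    make_octahedral_ca_site,
    make_synthetic_blade,
)


def rigid_transform(chain: ChainModel, rng) -> ChainModel:
    """Apply a random rotation + translation to every coordinate."""
    # random rotation from QR decomposition
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    import copy

    moved = copy.deepcopy(chain)
    for res in moved.residues:
        for k in res.atoms:
            res.atoms[k] = q @ res.atoms[k] + t
    moved.waters = [q @ w + t for w in moved.waters]
    moved.ions = {k: (e, q @ c + t) for k, (e, c) in moved.ions.items()}
    return moved


def circ_err(a, b):
    return abs(((a - b + 180.0) % 360.0) - 180.0)


class TestTorsions:
    def test_round_trip_random_angles(self, rng):
        angles = [(float(a), float(b)) for a, b in rng.uniform(-179, 179, (12, 2))]
        chain = build_backbone(angles)
        tors = compute_backbone_torsions(chain)
        for i, t in enumerate(tors):
            if t.phi is not None:
                assert circ_err(t.phi, angles[i][0]) < 1e-4
            if t.psi is not None:
                assert circ_err(t.psi, angles[i][1]) < 1e-4

    def test_terminal_angles_undefined(self, rng):
        chain = build_backbone([(-60.0, -40.0)] * 5)
        tors = compute_backbone_torsions(chain)
        assert tors[0].phi is None and tors[0].psi is not None
        assert tors[-1].psi is None and tors[-1].phi is not None

    def test_agrees_with_gemmi_dihedral(self, rng):
        import gemmi

        for _ in range(30):
            pts = rng.normal(size=(4, 3)) * 4
            mine = dihedral(*pts)
            ref = math.degrees(
                gemmi.calculate_dihedral(*[gemmi.Position(*p) for p in pts])
            )
            assert circ_err(mine, ref) < 1e-9

    def test_rigid_motion_invariance(self, rng):
        chain = build_backbone([(-70.0, 130.0)] * 8)
        moved = rigid_transform(chain, rng)
        t0 = compute_backbone_torsions(chain)
        t1 = compute_backbone_torsions(moved)
        for a, b in zip(t0, t1):
            if a.phi is not None:
                assert circ_err(a.phi, b.phi) < 1e-6
            if a.psi is not None:
                assert circ_err(a.psi, b.psi) < 1e-6

    def test_chain_break_yields_undefined_flanks(self, rng):
        chain = build_backbone([(-60.0, -40.0)] * 6)
        # translate the second half far away: C(2)-N(3) >> 2.5 A
        for res in chain.residues[3:]:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([50.0, 0, 0])
        tors = compute_backbone_torsions(chain)
        assert tors[2].psi is None and tors[3].phi is None
        assert tors[1].psi is not None and tors[4].phi is not None

    def test_missing_backbone_atom_handled(self):
        chain = build_backbone([(-60.0, -40.0)] * 4)
        del chain.residues[1].atoms["CA"]
        tors = compute_backbone_torsions(chain)
        assert tors[1].phi is None and tors[1].psi is None


class TestTurnClassifier:
    @pytest.mark.parametrize("definition", TURN_TYPES, ids=lambda d: d.name)
    def test_canonical_angles_are_fixed_points(self, definition):
        a = classify_beta_turn(definition.canonical)
        assert a.strict_type == definition.name
        assert a.nearest_type == definition.name
        assert a.angular_distance == 0.0

    def test_type_ii_canonical(self):
        a = classify_beta_turn((-60.0, 120.0, 90.0, 0.0))
        assert a.strict_type == "II"

    def test_type_i_canonical(self):
        a = classify_beta_turn((-60.0, -30.0, -90.0, 0.0))
        assert a.strict_type == "I"

    def test_nonstandard_turn_nearest_type_ii(self):
        # a distorted proline turn: outside strict tolerance of every type,
        # but closest to type II
        a = classify_beta_turn((-57.0, 163.0, 64.0, 32.0))
        assert a.strict_type is None
        assert a.nearest_type == "II"

    def test_single_angle_relaxation(self):
        # one angle 40 deg off is tolerated, two are not
        assert classify_beta_turn((-60.0, 160.0, 90.0, 0.0)).strict_type == "II"
        assert classify_beta_turn((-60.0, 160.0, 130.0, 0.0)).strict_type is None

    def test_undefined_torsions_error(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_beta_turn((None, 120.0, 90.0, 0.0))

    @pytest.mark.parametrize("name", ["I", "II", "I'", "II'"])
    def test_construct_then_classify_round_trip(self, name):
        chain = generate_turn_coords(name)
        tors = compute_backbone_torsions(chain)
        a = classify_window_from_chain(chain, tors, 1)
        assert a.strict_type == name
        assert a.is_turn  # CA1-CA4 within 7 A for canonical turns

    def test_construct_explicit_exception_angles(self):
        chain = generate_turn_coords((-57.0, 163.0, 64.0, 32.0))
        tors = compute_backbone_torsions(chain)
        a = classify_window_from_chain(chain, tors, 1)
        assert a.strict_type is None and a.nearest_type == "II"


class TestHBonds:
    def test_synthetic_blade_network(self):
        chain, ann, _ = make_synthetic_blade()
        bonds = detect_mainchain_hbonds(chain, ann)
        assert count_intersegment_hbonds(bonds) == 5
        assert sum(b.intra_turn for b in bonds) == 2
        assert len(bonds) == 7

    def test_each_bond_listed_once(self):
        chain, ann, _ = make_synthetic_blade()
        bonds = detect_mainchain_hbonds(chain, ann)
        pairs = [(b.donor_seqid, b.acceptor_seqid) for b in bonds]
        assert len(pairs) == len(set(pairs))

    def test_distant_segments_yield_none(self):
        # two turn windows 10 A apart: no inter-segment bonds
        a = build_backbone([(-120, 140), (-60, 120), (90, 0), (-120, 140)],
                           start_seqid=10)
        b = build_backbone([(-120, 140), (-60, -30), (-90, 0), (-120, 140)],
                           start_seqid=20)
        for res in b.residues:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([0.0, 10.0, 0.0])
        chain = ChainModel(chain_id="A", residues=a.residues + b.residues)
        ann = BladeAnnotation(
            chain_id="A", blade=1,
            segments={**{f"A{k}": 9 + k for k in range(5)},
                      **{f"B{k}": 19 + k for k in range(5)},
                      "C1": 30, "C2": 31},
        )
        bonds = detect_mainchain_hbonds(chain, ann)
        assert count_intersegment_hbonds(bonds) == 0

    def test_rigid_motion_invariance(self, rng):
        chain, ann, _ = make_synthetic_blade()
        moved = rigid_transform(chain, rng)
        b0 = detect_mainchain_hbonds(chain, ann)
        b1 = detect_mainchain_hbonds(moved, ann)
        assert [(b.donor_seqid, b.acceptor_seqid) for b in b0] == [
            (b.donor_seqid, b.acceptor_seqid) for b in b1
        ]

    def test_count_non_increasing_as_cutoff_tightens(self):
        chain, ann, _ = make_synthetic_blade()
        counts = [
            len(detect_mainchain_hbonds(chain, ann, HBondCriteria(max_no_distance=d)))
            for d in (3.5, 3.3, 3.1, 2.9, 2.5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCaSite:
    def test_octahedral_site(self):
        chain, ann = make_octahedral_ca_site()
        rep = verify_ca_site(chain, ann)
        assert rep.site_present
        assert rep.n_ligands == 6
        assert rep.bridging_water
        assert rep.loop34_glycine_contact
        assert [d for _, d in rep.ligands] == sorted(d for _, d in rep.ligands)

    def test_no_ion_annotated(self):
        chain, ann = make_octahedral_ca_site()
        ann.ca_ion = None
        rep = verify_ca_site(chain, ann)
        assert not rep.site_present and rep.n_ligands == 0

    def test_shell_shrinks_with_cutoff(self):
        chain, ann = make_octahedral_ca_site()
        loose = verify_ca_site(chain, ann, CaSiteCriteria(coordination_max=3.0))
        tight = verify_ca_site(chain, ann, CaSiteCriteria(coordination_max=2.0))
        assert tight.n_ligands <= loose.n_ligands

    def test_rigid_motion_invariance(self, rng):
        chain, ann = make_octahedral_ca_site()
        moved = rigid_transform(chain, rng)
        r0, r1 = verify_ca_site(chain, ann), verify_ca_site(moved, ann)
        assert r0.n_ligands == r1.n_ligands
        assert r0.bridging_water == r1.bridging_water


class TestVerdicts:
    def test_synthetic_blade_passes_all_four(self):
        chain, ann, seq = make_synthetic_blade()
        v = verify_blade(chain, ann, sequence=seq)
        assert v.char1_cage and v.char2_turns
        assert v.char3_hbond_network and v.char4_ca_motif
        assert v.all_pass
        assert v.n_intersegment_hbonds == 5

    def test_separated_segments_fail_hbond_characteristic(self):
        chain, ann, seq = make_synthetic_blade(separated=True)
        v = verify_blade(chain, ann, sequence=seq)
        assert not v.char3_hbond_network
        assert v.char2_turns  # turn geometry untouched

    def test_cage_free_sequence_fails_characteristic_1(self):
        chain, ann, _ = make_synthetic_blade()
        v = verify_blade(chain, ann, sequence="L" * 80)
        assert not v.char1_cage and not v.char4_ca_motif

    def test_incomplete_annotation_errors(self):
        chain, ann, seq = make_synthetic_blade()
        del ann.segments["B2"]
        with pytest.raises(ValueError, match="B2"):
            verify_blade(chain, ann, sequence=seq)

    def test_verdict_invariant_under_rigid_motion(self, rng):
        chain, ann, seq = make_synthetic_blade()
        moved = rigid_transform(chain, rng)
        v0 = verify_blade(chain, ann, sequence=seq)
        v1 = verify_blade(moved, ann, sequence=seq)
        assert (v0.char1_cage, v0.char2_turns, v0.char3_hbond_network,
                v0.char4_ca_motif) == (
            v1.char1_cage, v1.char2_turns, v1.char3_hbond_network,
            v1.char4_ca_motif)


def build_domain(with_ring_closure: bool):
    """Seven synthetic blades in one chain; optional N-terminal strand that
    pairs with strand 3 of blade 7 (ring closure, characteristic 5)."""
    chain = ChainModel(chain_id="A")
    annotations = []
    seqs = []
    offset = 20
    for b in range(7):
        frag, ann, seq = make_synthetic_blade(seed=b, offset=offset)
        # keep blades spatially separate
        for res in frag.residues:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([0.0, 0.0, 40.0 * b])
        ann.blade = b + 1
        chain.residues.extend(frag.residues)
        annotations.append(ann)
        seqs.append(seq)
        offset += len(seq)
    # strand 3 of blade 7: a straight CA trace
    s3_start = offset + 5
    base = np.array([100.0, 0.0, 0.0])
    for i in range(5):
        from fggap.structure import Residue

        r = Residue(seqid=s3_start + i, name="VAL")
        r.atoms["CA"] = base + np.array([3.8 * i, 0.0, 0.0])
        r.elements["CA"] = "C"
        chain.residues.append(r)
    annotations[6].strands[3] = (s3_start, s3_start + 4)
    blade1_start = annotations[0].span[0]
    if with_ring_closure:
        from fggap.structure import Residue

        for j, i in enumerate(range(blade1_start - 5, blade1_start)):
            r = Residue(seqid=i, name="ILE")
            r.atoms["CA"] = base + np.array([3.8 * j, 4.8, 0.0])
            r.elements["CA"] = "C"
            chain.residues.append(r)
    chain.residues.sort(key=lambda r: r.seqid)
    sequence = "L" * 19 + "".join(seqs) + "L" * 20
    return chain, annotations, sequence


class TestDomainVerdict:
    def test_seven_blades_aggregate(self):
        chain, anns, seq = build_domain(with_ring_closure=True)
        dv = verify_domain(chain, anns, sequence=seq)
        assert len(dv.blades) == 7
        assert all(v.char2_turns for v in dv.blades)
        assert dv.characteristic5

    def test_no_ring_closure(self):
        chain, anns, seq = build_domain(with_ring_closure=False)
        dv = verify_domain(chain, anns, sequence=seq)
        assert not dv.characteristic5

    def test_wrong_blade_count_errors(self):
        chain, anns, seq = build_domain(with_ring_closure=False)
        with pytest.raises(ValueError, match="7"):
            verify_domain(chain, anns[:5], sequence=seq)


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        text = (
            "chain\tblade\telement\tstart\tend\n"
            "A\t1\tstrand1\t5\t10\n"
            "A\t1\tA1\t12\t12\n"
            "A\t1\tA2\t13\t13\n"
            "A\t1\tcaloop34\t40\t44\n"
            "A\t1\tca_ion\t900\t900\n"
            "B\t2\tB2\t7\t7\n"
        )
        path = tmp_path / "ann.tsv"
        path.write_text(text)
        ann = read_annotation(path)
        assert ann["A"][1].strands[1] == (5, 10)
        assert ann["A"][1].segments["A2"] == 13
        assert ann["A"][1].ca_loop34 == (40, 44)
        assert ann["A"][1].ca_ion == 900
        assert ann["B"][2].segments["B2"] == 7

    def test_unknown_element_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\t1\tstrand9\t1\t2\n")
        with pytest.raises(ValueError, match="strand9"):
            read_annotation(path)


class TestStructureIO:
    def test_pdb_round_trip_preserves_torsions(self, tmp_path, rng):
        from fggap.io import chain_to_pdb

        angles = [(float(a), float(b)) for a, b in rng.uniform(-170, 170, (6, 2))]
        chain = build_backbone(angles)
        path = tmp_path / "synthetic.pdb"
        chain_to_pdb(chain, path)
        st = load_structure(path)
        loaded = extract_chain(st, "A")
        t0 = compute_backbone_torsions(chain)
        t1 = compute_backbone_torsions(loaded)
        for a, b in zip(t0, t1):
            if a.phi is not None:
                assert circ_err(a.phi, b.phi) < 0.05  # PDB 1e-3 A coordinates
            if a.psi is not None:
                assert circ_err(a.psi, b.psi) < 0.05

    def test_ion_and_water_round_trip(self, tmp_path):
        from fggap.io import chain_to_pdb

        chain, ann = make_octahedral_ca_site()
        path = tmp_path / "site.pdb"
        chain_to_pdb(chain, path)
        loaded = extract_chain(load_structure(path), "A")
        assert len(loaded.waters) == 1
        assert any(e == "CA" for e, _ in loaded.ions.values())
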