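"""Hydrogen-bond detection: distance criterion, CH···O geometry, water
coordination and per-conformer networks, cross-checked against a
brute-force all-pairs oracle."""

import math

import numpy as np
import pytest

import retgeom as rg
from retgeom.errors import AtomNotFoundError, ConstructionError
from retgeom.hbonds import _altlocs_compatible, _intra_excluded, polar_atoms

from conftest import random_rigid_motion


def brute_force_hbonds(model, cutoff):
    """Independent all-pairs oracle with the same exclusion rules."""
    atoms = polar_atoms(model)
    out = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            if not _altlocs_compatible(a, b) or _intra_excluded(a, b):
                continue
            d = float(np.linalg.norm(a.pos - b.pos))
            if d <= cutoff:
                out.add((frozenset({a.full_key, b.full_key}), round(d, 9)))
    return out


class TestFindHBonds:
    def test_far_apart_oxygens_no_bond(self):
        m = rg.generate_hbond_cluster(
            [rg.PairSpec(("HOH", 1, "O"), ("HOH", 2, "O"), 5.0)])
        assert rg.find_hbonds(m, cutoff=3.2) == []

    def test_constructed_distances_detected_exactly(self):
        m = rg.generate_hbond_cluster([
            rg.PairSpec(("GLU", 194, "OE2"), ("GLU", 204, "OE2"), 2.40),
            rg.PairSpec(("GLU", 194, "OE1"), ("GLU", 204, "OE1"), 2.67),
            rg.PairSpec(("HOH", 403, "O"), ("SER", 141, "OG"), 3.50),
        ])
        bonds = rg.find_hbonds(m, cutoff=3.2)
        assert [round(b.distance, 2) for b in bonds] == [2.40, 2.67]
        assert bonds[0].short_flag and not bonds[1].short_flag

    def test_short_flag_threshold(self):
        m = rg.generate_hbond_cluster(
            [rg.PairSpec(("HOH", 1, "O"), ("HOH", 2, "O"), 2.49),
             rg.PairSpec(("HOH", 3, "O"), ("HOH", 4, "O"), 2.51)])
        flags = {round(b.distance, 2): b.short_flag for b in rg.find_hbonds(m)}
        assert flags == {2.49: True, 2.51: False}

    def test_carboxylate_intra_pair_excluded(self):
        mk = lambda s, name, x: rg.AtomRecord(serial=s, name=name, altloc="",
                                              res_name="ASP", chain_id="A", res_seq=85,
                                              icode="", pos=np.array([x, 0.0, 0.0]),
                                              occupancy=1.0, b_iso=10.0, element="O")
        m = rg.StructureModel(atoms=[mk(1, "OD1", 0.0), mk(2, "OD2", 2.2)])
        assert rg.find_hbonds(m) == []

    def test_donor_acceptor_orientation(self):
        m = rg.generate_hbond_cluster(
            [rg.PairSpec(("ASP", 85, "OD2"), ("LYS", 216, "NZ"), 2.9)])
        (bond,) = rg.find_hbonds(m)
        assert bond.donor.name == "NZ" and bond.acceptor.name == "OD2"

    def test_monotone_in_cutoff(self, water_box_model):
        prev: set = set()
        for cutoff in (2.6, 3.0, 3.4, 4.0):
            cur = {frozenset({b.donor.full_key, b.acceptor.full_key})
                   for b in rg.find_hbonds(water_box_model, cutoff)}
            assert prev <= cur
            prev = cur

    def test_matches_brute_force_oracle(self, water_box_model):
        bonds = rg.find_hbonds(water_box_model, cutoff=3.2)
        mine = {(frozenset({b.donor.full_key, b.acceptor.full_key}), round(b.distance, 9))
                for b in bonds}
        assert mine == brute_force_hbonds(water_box_model, 3.2)

    def test_invariant_under_reordering_and_rigid_motion(self, water_box_model, rng):
        ref = {frozenset({b.donor.full_key, b.acceptor.full_key})
               for b in rg.find_hbonds(water_box_model, 3.2)}
        perm = rng.permutation(len(water_box_model.atoms))
        rot, trans = random_rigid_motion(rng)
        moved = water_box_model.with_atoms(
            [water_box_model.atoms[i].moved_to(water_box_model.atoms[i].pos @ rot.T + trans)
             for i in perm])
        got = {frozenset({b.donor.full_key, b.acceptor.full_key})
               for b in rg.find_hbonds(moved, 3.2)}
        assert got == ref


def _sp2_carbon_model(o_pos):
    """A vinylic carbon with two in-plane neighbors plus one oxygen."""
    mk = lambda s, name, res, seq, pos, el: rg.AtomRecord(
        serial=s, name=name, altloc="", res_name=res, chain_id="A", res_seq=seq,
        icode="", pos=np.asarray(pos, float), occupancy=1.0, b_iso=10.0, element=el)
    atoms = [
        mk(1, "C14", "RET", 300, (0.0, 0.0, 0.0), "C"),
        mk(2, "C13", "RET", 300, (-1.26, 0.74, 0.0), "C"),
        mk(3, "C15", "RET", 300, (1.26, 0.74, 0.0), "C"),
        mk(4, "OD1", "ASP", 212, o_pos, "O"),
    ]
    return rg.StructureModel(atoms=atoms)


class TestChOContacts:
    def test_collinear_geometry_angle_180(self):
        # H sits at (0, -1, 0); O straight beyond it
        m = _sp2_carbon_model((0.0, -3.3, 0.0))
        (contact,) = rg.ch_o_contacts(m, m.find_atoms(name="C14"), m.find_atoms(name="OD1"))
        assert contact.angle_dha == pytest.approx(180.0)
        assert contact.distance == pytest.approx(3.3)

    def test_inverse_constructed_130_degrees(self):
        # place O so that the C-H...O angle is exactly 130 deg and C...O = 3.30 A:
        # law of cosines about the known H at (0,-1,0)
        target_angle, c_o = 130.0, 3.30
        ch = 1.0
        cosg = math.cos(math.radians(target_angle))
        r = (-(-2 * ch * cosg) + math.sqrt((2 * ch * cosg) ** 2 - 4 * (ch ** 2 - c_o ** 2))) / 2
        h = np.array([0.0, -1.0, 0.0])
        # direction from H making 130 deg with the H->C vector, in-plane
        u_hc = np.array([0.0, 1.0, 0.0])
        direction = np.array([math.sin(math.radians(target_angle)), 0.0, 0.0]) \
            + u_hc * math.cos(math.radians(target_angle))
        o_pos = h + r * direction / np.linalg.norm(direction)
        m = _sp2_carbon_model(o_pos)
        (contact,) = rg.ch_o_contacts(m, m.find_atoms(name="C14"), m.find_atoms(name="OD1"))
        assert contact.distance == pytest.approx(3.30, abs=1e-9)
        assert contact.angle_dha == pytest.approx(130.0, abs=0.1)

    def test_carbon_without_two_neighbors_flagged(self):
        m = _sp2_carbon_model((0.0, -3.3, 0.0))
        m2 = m.with_atoms([a for a in m.atoms if a.name != "C13"])
        (contact,) = rg.ch_o_contacts(m2, m2.find_atoms(name="C14"), m2.find_atoms(name="OD1"))
        assert contact.angle_missing and contact.angle_dha is None

    def test_beyond_cutoff_skipped(self):
        m = _sp2_carbon_model((0.0, -4.0, 0.0))
        assert rg.ch_o_contacts(m, m.find_atoms(name="C14"),
                                m.find_atoms(name="OD1"), dist_cutoff=3.5) == []


class TestWaterCoordination:
    def test_isolated_water(self):
        m = rg.generate_hbond_cluster(
            [rg.PairSpec(("HOH", 402, "O"), ("HOH", 500, "O"), 9.0)])
        summ = rg.water_coordination(m, 402, cutoff=3.2)
        assert summ.count == 0 and not summ.complete

    def test_tetrahedral_water_complete(self):
        center = np.zeros(3)
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3) * 2.8
        atoms = [rg.AtomRecord(serial=1, name="O", altloc="", res_name="HOH", chain_id="A",
                               res_seq=402, icode="", pos=center, occupancy=1.0,
                               b_iso=10.0, element="O")]
        for i, v in enumerate(verts):
            atoms.append(rg.AtomRecord(serial=i + 2, name="O", altloc="", res_name="HOH",
                                       chain_id="A", res_seq=500 + i, icode="", pos=v,
                                       occupancy=1.0, b_iso=10.0, element="O"))
        summ = rg.water_coordination(rg.StructureModel(atoms=atoms), 402)
        assert summ.count == 4 and summ.complete

    def test_three_partner_active_site_water_incomplete(self):
        # a Schiff-base-like water: three polar partners only
        m = rg.generate_hbond_cluster([
            rg.PairSpec(("HOH", 402, "O"), ("LYS", 216, "NZ"), 2.77),
            rg.PairSpec(("HOH", 402, "O"), ("ASP", 85, "OD2"), 2.8),
            rg.PairSpec(("HOH", 402, "O"), ("ASP", 212, "OD1"), 3.0),
        ])
        summ = rg.water_coordination(m, 402)
        assert summ.count == 3 and not summ.complete
        assert {a.name for a in summ.partners} == {"NZ", "OD2", "OD1"}

    def test_missing_water_raises(self):
        m = rg.generate_hbond_cluster(
            [rg.PairSpec(("HOH", 402, "O"), ("ASP", 85, "OD2"), 2.8)])
        with pytest.raises(AtomNotFoundError):
            rg.water_coordination(m, 999)


class TestConformerNetworks:
    def test_no_altlocs_single_blank_network(self):
        m = rg.generate_hbond_cluster(
            [rg.PairSpec(("HOH", 1, "O"), ("HOH", 2, "O"), 2.8)])
        nets = rg.conformer_networks(m)
        assert list(nets) == [""]
        assert len(nets[""].bonds) == 1

    def test_two_conformer_cluster(self):
        m = rg.generate_hbond_cluster([
            rg.PairSpec(("GLU", 194, "OE2"), ("GLU", 204, "OE2"), 2.40,
                        altloc="A", occupancy=0.55),
            rg.PairSpec(("GLU", 194, "OE2"), ("GLU", 204, "OE2"), 3.00,
                        altloc="B", occupancy=0.45),
        ])
        nets = rg.conformer_networks(m)
        assert set(nets) == {"A", "B"}
        assert nets["A"].occupancy == pytest.approx(0.55)
        assert nets["B"].occupancy == pytest.approx(0.45)
        assert [round(b.distance, 2) for b in nets["A"].bonds] == [2.40]
        assert nets["A"].bonds[0].short_flag
        assert [round(b.distance, 2) for b in nets["B"].bonds] == [3.00]

    def test_blank_atoms_shared_between_networks(self):
        m = rg.generate_hbond_cluster([
            rg.PairSpec(("HOH", 401, "O"), ("ASP", 85, "OD2"), 2.8),          # blank pair
            rg.PairSpec(("GLU", 204, "OE1"), ("HOH", 404, "O"), 2.7, altloc="A", occupancy=0.5),
            rg.PairSpec(("GLU", 204, "OE1"), ("HOH", 404, "O"), 3.1, altloc="B", occupancy=0.5),
        ])
        nets = rg.conformer_networks(m)
        for lab in ("A", "B"):
            blank_bonds = [b for b in nets[lab].bonds
                           if not b.donor.altloc and not b.acceptor.altloc]
            assert len(blank_bonds) == 1


class TestClusterGenerator:
    def test_exact_distance(self):
        m = rg.generate_hbond_cluster(
            [rg.PairSpec(("HOH", 1, "O"), ("HOH", 2, "O"), 2.40)])
        a, b = m.atoms
        assert rg.distance(a.pos, b.pos) == pytest.approx(2.40, abs=1e-12)

    def test_empty_spec_empty_model(self):
        assert len(rg.generate_hbond_cluster([])) == 0

    def test_conflicting_placement_rejected(self):
        pairs = [rg.PairSpec(("HOH", 1, "O"), ("HOH", 2, "O"), 2.40),
                 rg.PairSpec(("HOH", 1, "O"), ("HOH", 2, "O"), 3.00)]
        with pytest.raises(ConstructionError):
            rg.generate_hbond_cluster(pairs)

    def test_too_short_distance_rejected(self):
        with pytest.raises(ConstructionError):
            rg.PairSpec(("HOH", 1, "O"), ("HOH", 2, "O"), 1.2)
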