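"""Vector geometry: dihedral convention, hydrogen placement, Kabsch
superposition and C-alpha RMSD, each cross-checked against an
independent oracle."""

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral

import retgeom as rg
from retgeom.errors import (
    InsufficientAtomsError,
    UndefinedGeometryError,
    UnsupportedHybridizationError,
)

from conftest import random_rigid_motion


class TestDistanceAndAngle:
    def test_three_four_five(self):
        assert rg.distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
        assert rg.distance((1, 1, 1), (1, 1, 1)) == 0.0

    def test_right_angle(self):
        assert rg.angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)


class TestDihedral:
    def test_planar_anti_is_180(self):
        val = rg.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        assert val == pytest.approx(180.0)

    def test_planar_syn_is_0(self):
        val = rg.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        assert val == pytest.approx(0.0)

    def test_right_handed_sign(self):
        # d rotated +90 deg about the b->c (x) axis from the syn position
        val = rg.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1))
        assert val == pytest.approx(90.0)

    def test_agrees_with_independent_oracle(self, rng):
        worst = 0.0
        for _ in range(1000):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                mine = rg.dihedral(*pts)
            except UndefinedGeometryError:
                continue
            ref = np.degrees(calc_dihedral(*[Vector(*p) for p in pts]))
            diff = abs(mine - ref) % 360.0
            worst = max(worst, min(diff, 360.0 - diff))
        assert worst < 1e-9

    def test_reversal_symmetry_and_mirror_antisymmetry(self, rng):
        for _ in range(100):
            pts = rng.normal(size=(4, 3))
            val = rg.dihedral(*pts)
            assert rg.dihedral(*pts[::-1]) == pytest.approx(val, abs=1e-9)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert rg.dihedral(*mirrored) == pytest.approx(
                -val if abs(val) < 180.0 else val, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(4, 3))
        val = rg.dihedral(*pts)
        for _ in range(20):
            rot, trans = random_rigid_motion(rng)
            moved = pts @ rot.T + trans
            assert rg.dihedral(*moved) == pytest.approx(val, abs=1e-8)
            assert rg.distance(moved[0], moved[3]) == pytest.approx(
                rg.distance(pts[0], pts[3]), abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(UndefinedGeometryError):
            rg.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestVinylicHydrogen:
    def test_symmetric_case(self):
        h = rg.place_vinylic_hydrogen((0, 0, 0), (-1.26, 0.74, 0), (1.26, 0.74, 0))
        np.testing.assert_allclose(h, [0.0, -1.0, 0.0], atol=1e-12)

    def test_bond_length_and_equidistance(self, rng):
        for _ in range(200):
            c = rng.normal(size=3)
            # two neighbors at random sp2-ish geometry
            a = c + rng.normal(size=3)
            b = c + rng.normal(size=3)
            try:
                h = rg.place_vinylic_hydrogen(c, a, b)
            except UnsupportedHybridizationError:
                continue
            assert np.linalg.norm(h - c) == pytest.approx(1.0, abs=1e-12)
            # external bisector: equal angles to both neighbor directions
            ua = (a - c) / np.linalg.norm(a - c)
            ub = (b - c) / np.linalg.norm(b - c)
            uh = h - c
            assert np.dot(uh, ua) == pytest.approx(np.dot(uh, ub), abs=1e-9)
            # in-plane
            n = np.cross(ua, ub)
            assert abs(np.dot(uh, n / np.linalg.norm(n))) < 1e-9

    def test_collinear_neighbors_rejected(self):
        with pytest.raises(UnsupportedHybridizationError):
            rg.place_vinylic_hydrogen((0, 0, 0), (1, 0, 0), (2, 0, 0))


def quaternion_superpose_rmsd(a, b):
    """Independent oracle: Horn's closed-form quaternion method."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    sq = np.sum(a ** 2) + np.sum(b ** 2) - 2.0 * lam
    return np.sqrt(max(sq, 0.0) / a.shape[0])


class TestKabsch:
    def test_identical_sets(self, rng):
        a = rng.normal(size=(10, 3))
        res = rg.kabsch_superpose(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_gives_zero(self, rng):
        a = rng.normal(size=(30, 3))
        rot, trans = random_rigid_motion(rng)
        res = rg.kabsch_superpose(a, a @ rot.T + trans)
        assert res.rmsd < 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            res = rg.kabsch_superpose(a, b)
            assert res.rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-9)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_never_worse_than_untransformed(self, rng):
        for _ in range(20):
            a = rng.normal(size=(15, 3))
            b = rng.normal(size=(15, 3))
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert rg.kabsch_superpose(a, b).rmsd <= raw + 1e-12

    def test_too_few_atoms(self):
        with pytest.raises(InsufficientAtomsError):
            rg.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _calpha_model(n, rng, label=""):
    atoms = []
    for i in range(n):
        atoms.append(rg.AtomRecord(serial=i + 1, name="CA", altloc="", res_name="ALA",
                                   chain_id="A", res_seq=i + 1, icode="",
                                   pos=rng.uniform(0, 40, size=3), occupancy=1.0,
                                   b_iso=10.0, element="C"))
    return rg.StructureModel(atoms=atoms, label=label)


class TestCommonCalphaRmsd:
    def test_self_is_zero(self, rng):
        m = _calpha_model(50, rng)
        r, n = rg.rmsd_common_calpha(m, m)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert n == 50

    def test_strict_intersection_pairing(self, rng):
        m = _calpha_model(50, rng)
        # drop a loop from the second model; rmsd still 0 over the rest
        partial = m.with_atoms([a for a in m.atoms if not 20 <= a.res_seq <= 25])
        r, n = rg.rmsd_common_calpha(m, partial)
        assert n == 44 and r == pytest.approx(0.0, abs=1e-12)

    def test_noise_statistics(self, rng):
        # rmsd of a sigma-per-axis perturbed copy approaches sigma*sqrt(3)
        sigma = 0.1
        m = _calpha_model(200, rng)
        vals = []
        for seed in range(30):
            rep = rg.perturb_replicates(m, sigma, 1, seed=seed)[0]
            r, _ = rg.rmsd_common_calpha(m, rep)
            vals.append(r)
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_insufficient_overlap(self, rng):
        a = _calpha_model(10, rng)
        b = a.with_atoms([x for x in a.atoms if x.res_seq > 8])
        with pytest.raises(InsufficientAtomsError):
            rg.rmsd_common_calpha(a, b)
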