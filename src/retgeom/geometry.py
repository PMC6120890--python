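"""Exact vector geometry: distances, angles, dihedrals, hydrogen placement
and least-squares (Kabsch) superposition.

All lengths are in angstrom and all angles in degrees.  Dihedral signs
follow the right-handed IUPAC convention, reported in (−180, 180] with
+180 preferred over −180.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientAtomsError, UndefinedGeometryError, UnsupportedHybridizationError
from .model import AltlocPolicy, StructureModel, resolve_altlocs

# cross-product norm below this (A^2) means collinear points
_DEGENERATE_CROSS = 1e-10


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance |a − b| in angstrom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c at vertex b, in degrees within [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedGeometryError("zero-length bond vector in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def wrap_angle(deg: float) -> float:
    """Wrap into (−180, 180], preferring +180 over −180."""
    w = float(np.remainder(deg, 360.0))
    if w > 180.0:
        w -= 360.0
    if w == -180.0:
        w = 180.0
    return w


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle of a–b–c–d about the b→c axis, degrees in (−180, 180].

    Positive when, looking from b toward c, the far bond c→d is rotated
    clockwise from the near bond b→a (IUPAC right-handed convention).
    Raises :class:`UndefinedGeometryError` when three consecutive points
    are collinear.
    """
    p = [np.asarray(x, dtype=float) for x in (a, b, c, d)]
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    if (np.linalg.norm(np.cross(b1, b2)) < _DEGENERATE_CROSS
            or np.linalg.norm(np.cross(b2, b3)) < _DEGENERATE_CROSS):
        raise UndefinedGeometryError("collinear points: dihedral undefined")
    # atan2 formulation is numerically stable near 0 and 180
    b2u = b2 / np.linalg.norm(b2)
    v = -b1 - np.dot(-b1, b2u) * b2u
    w = b3 - np.dot(b3, b2u) * b2u
    x = np.dot(v, w)
    y = np.dot(np.cross(b2u, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_vinylic_hydrogen(c: np.ndarray, neighbor_a: np.ndarray, neighbor_b: np.ndarray,
                           bond_length: float = 1.0) -> np.ndarray:
    """Place the hydrogen of an sp2 (vinylic) carbon.

    The H sits in the plane of the carbon and its two heavy neighbors,
    ``bond_length`` angstrom from the carbon along the external bisector
    of the neighbor–C–neighbor angle.  The default 1.0 A is the standard
    C–H bond length used when inferring hydrogens absent from X-ray
    models.
    """
    c = np.asarray(c, dtype=float)
    u = np.asarray(neighbor_a, dtype=float) - c
    v = np.asarray(neighbor_b, dtype=float) - c
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UnsupportedHybridizationError("neighbor coincides with the carbon")
    if np.linalg.norm(np.cross(u / nu, v / nv)) < _DEGENERATE_CROSS:
        raise UnsupportedHybridizationError("collinear neighbors: sp2 plane undefined")
    bisector = u / nu + v / nv
    nb = np.linalg.norm(bisector)
    if nb < 1e-12:
        raise UnsupportedHybridizationError("neighbors exactly opposed: bisector undefined")
    return c - bisector / nb * bond_length


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body superposition of one coordinate set onto another."""

    rotation: np.ndarray     # 3x3 proper rotation (det = +1)
    translation: np.ndarray  # 3-vector: apply as R @ x + t
    rmsd: float              # angstrom, after the transform
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``coords_a`` onto ``coords_b`` (Kabsch).

    Returns the proper rotation (reflections excluded) and translation
    minimizing the RMSD of ``R a + t`` against ``b``.  Requires N >= 3.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InsufficientAtomsError("coordinate sets must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise InsufficientAtomsError(f"need at least 3 atoms, got {n}")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    moved = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def rmsd_common_calpha(model_a: StructureModel, model_b: StructureModel) -> tuple[float, int]:
    """Superpose two models on their shared C-alpha atoms and return (rmsd, n_pairs).

    C-alphas are paired by (chain, res_seq, icode) intersection — the
    strict intersection, so residues absent from either model (disordered
    loops, termini) are simply not compared.  Altloc C-alphas are resolved
    to the highest-occupancy conformer before pairing.
    """
    ca_a = {a.residue_key: a for a in resolve_altlocs(
        [x for x in model_a.atoms if x.name == "CA" and x.is_amino],
        AltlocPolicy.HIGHEST_OCCUPANCY)}
    ca_b = {a.residue_key: a for a in resolve_altlocs(
        [x for x in model_b.atoms if x.name == "CA" and x.is_amino],
        AltlocPolicy.HIGHEST_OCCUPANCY)}
    common = [k for k in ca_a if k in ca_b]
    if len(common) < 3:
        raise InsufficientAtomsError(
            f"only {len(common)} common C-alpha atoms; need at least 3")
    common.sort()
    pa = np.stack([ca_a[k].pos for k in common])
    pb = np.stack([ca_b[k].pos for k in common])
    res = kabsch_superpose(pa, pb)
    return res.rmsd, res.n_atoms
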