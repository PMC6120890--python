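"""Torsion and helicity profiles along a conjugated polyene chain.

The retinal chromophore's color tuning depends on the planarity of its
conjugated backbone.  Per-bond deviation from planarity is expressed as
the helicity

    eta = wrap(180 - torsion) * (-1)^n

where ``torsion`` is the dihedral about the bond measured along the
main-chain path and ``n`` is the bond's ordinal parity index.  A planar
anti (trans) bond has eta = 0; the alternating sign makes a uniformly
twisted (helical) chain give a constant-sign profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import IncompatibleProfilesError, IncompleteChromophoreError
from .geometry import dihedral, distance, wrap_angle
from .model import AltlocPolicy, AtomRecord, StructureModel, resolve_altlocs

# Default conjugated path: beta-ionone end of retinal through the Schiff
# base to the first lysine side-chain carbon.  C4 and CE are anchors; the
# indexed bonds run C5-C6 ... C15-NZ.
DEFAULT_PATH = ("C4", "C5", "C6", "C7", "C8", "C9", "C10", "C11",
                "C12", "C13", "C14", "C15", "NZ", "CE")
# Side-chain atoms of the linking lysine live in a LYS residue, not RET.
_LYSINE_ATOMS = frozenset({"NZ", "CE", "CD", "CG", "CB"})


@dataclass(frozen=True)
class PolyeneDefinition:
    """Which atoms form the conjugated backbone and how bonds are numbered.

    ``bond_index_origin`` is the parity index n of the first indexed bond
    (the second–third path atom, C5–C6 by default).  The default of 1 is
    calibrated so that a reference ground-state chromophore with a
    +170-degree C5–C6 torsion gets a negative (−10 degree) helicity,
    matching the sign convention of published profiles.
    """

    path: tuple[str, ...] = DEFAULT_PATH
    retinal_res_name: str = "RET"
    bond_index_origin: int = 1
    max_bond_length: float = 2.0   # sanity check on consecutive path atoms

    def bond_labels(self) -> list[str]:
        return [f"{self.path[i]}-{self.path[i + 1]}" for i in range(1, len(self.path) - 2)]

    def bond_parities(self) -> list[int]:
        return [self.bond_index_origin + i for i in range(len(self.path) - 3)]


@dataclass(frozen=True)
class Torsion:
    """A signed dihedral over four named atoms, degrees in (−180, 180]."""

    atoms: tuple[str, str, str, str]
    value: float


@dataclass
class HelicityProfile:
    """Per-bond torsion and helicity, optionally averaged over an ensemble."""

    labels: list[str]
    parities: list[int]
    torsions: np.ndarray      # (n_models, n_bonds)
    etas: np.ndarray          # (n_models, n_bonds)
    model_labels: list[str] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return self.torsions.shape[0]

    @property
    def eta_mean(self) -> np.ndarray:
        return self.etas.mean(axis=0)

    @property
    def eta_sd(self) -> Optional[np.ndarray]:
        """Sample SD (n−1 denominator) across the ensemble; None for a single model."""
        if self.n_models < 2:
            return None
        return self.etas.std(axis=0, ddof=1)

    def eta_of(self, label: str) -> float:
        return float(self.eta_mean[self.labels.index(label)])


def resolve_path_atoms(model: StructureModel, defn: PolyeneDefinition) -> list[AtomRecord]:
    """Map the path's atom names onto the model's chromophore atoms.

    Carbon names are looked up in the retinal residue; lysine side-chain
    names (NZ, CE, ...) in LYS residues, choosing the conformer/copy
    nearest the previously resolved atom so that the covalently linked
    lysine is picked in a multi-copy model.  Altlocs resolve to the
    highest-occupancy conformer.
    """
    out: list[AtomRecord] = []
    for name in defn.path:
        if name in _LYSINE_ATOMS:
            cands = resolve_altlocs(model.find_atoms(name=name, res_name="LYS"),
                                    AltlocPolicy.HIGHEST_OCCUPANCY)
        else:
            cands = resolve_altlocs(model.find_atoms(name=name, res_name=defn.retinal_res_name),
                                    AltlocPolicy.HIGHEST_OCCUPANCY)
        if not cands:
            raise IncompleteChromophoreError(
                f"polyene path atom {name} missing from model {model.label or '<unnamed>'}")
        if len(cands) > 1 and out:
            cands = sorted(cands, key=lambda a: distance(a.pos, out[-1].pos))
        out.append(cands[0])
    for prev, cur in zip(out, out[1:]):
        d = distance(prev.pos, cur.pos)
        if d > defn.max_bond_length:
            raise IncompleteChromophoreError(
                f"path atoms {prev.name}-{cur.name} are {d:.2f} A apart; not bonded")
    return out


def polyene_torsions(model: StructureModel,
                     defn: PolyeneDefinition = PolyeneDefinition()) -> list[Torsion]:
    """Main-chain torsion for every indexed bond of the polyene.

    The torsion of bond i–(i+1) is the dihedral over path atoms
    (i−1, i, i+1, i+2) — always along the backbone, never via the methyl
    substituents at C9/C13.
    """
    atoms = resolve_path_atoms(model, defn)
    out = []
    for i in range(1, len(atoms) - 2):
        quad = atoms[i - 1:i + 3]
        val = dihedral(*(a.pos for a in quad))
        out.append(Torsion(atoms=tuple(a.name for a in quad), value=val))
    return out


def helicity(torsion: float, n: int) -> float:
    """eta = wrap(180 − torsion) · (−1)^n, degrees in (−180, 180]."""
    return wrap_angle(180.0 - torsion) * ((-1) ** (n % 2))


def torsion_from_helicity(eta: float, n: int) -> float:
    """Inverse of :func:`helicity`: the torsion giving ``eta`` at parity ``n``."""
    return wrap_angle(180.0 - eta * ((-1) ** (n % 2)))


def helicity_profile(models: Sequence[StructureModel],
                     defn: PolyeneDefinition = PolyeneDefinition()) -> HelicityProfile:
    """Per-bond torsion and helicity for each model, with ensemble mean/SD.

    SD uses the n−1 (sample) denominator, appropriate for error bars
    derived from a handful of independently refined replicates.
    """
    if not models:
        raise ValueError("need at least one model")
    labels = defn.bond_labels()
    parities = defn.bond_parities()
    tors = []
    for m in models:
        tvals = [t.value for t in polyene_torsions(m, defn)]
        tors.append(tvals)
    tarr = np.array(tors)
    earr = np.array([[helicity(t, n) for t, n in zip(row, parities)] for row in tarr])
    return HelicityProfile(labels=labels, parities=parities, torsions=tarr, etas=earr,
                           model_labels=[m.label for m in models])


@dataclass(frozen=True)
class ProfileDeviation:
    label: str
    delta_eta: float   # signed, profile_1 − profile_2 (of means)


def compare_profiles(p1: HelicityProfile, p2: HelicityProfile,
                     threshold: float = 5.0) -> list[ProfileDeviation]:
    """Bonds whose mean helicities differ by more than ``threshold`` degrees.

    Returns deviations sorted by |delta| descending; delta is signed
    (p1 − p2).  Profiles must share the same bond labels.
    """
    if p1.labels != p2.labels:
        raise IncompatibleProfilesError(
            f"bond labels differ: {p1.labels} vs {p2.labels}")
    deltas = p1.eta_mean - p2.eta_mean
    out = [ProfileDeviation(lab, float(d))
           for lab, d in zip(p1.labels, deltas) if abs(d) > threshold]
    out.sort(key=lambda x: abs(x.delta_eta), reverse=True)
    return out


def calibrate_parity(reference: StructureModel, defn: PolyeneDefinition = PolyeneDefinition(),
                     reference_bond: str = "C5-C6",
                     reference_sign: int = -1) -> PolyeneDefinition:
    """Fix the parity origin against a reference structure of known sign.

    The parity index n of the helicity formula is inherited from prior
    profiles without an absolute definition, so the origin is calibrated
    once: the returned definition gives ``reference_bond`` in the
    reference structure a helicity of the requested sign.  A zero
    reference helicity cannot fix the parity and raises ValueError.
    """
    prof = helicity_profile([reference], defn)
    eta = prof.eta_of(reference_bond)
    if eta == 0.0:
        raise ValueError(f"reference helicity at {reference_bond} is zero; parity undetermined")
    if np.sign(eta) == np.sign(reference_sign):
        return defn
    return replace(defn, bond_index_origin=defn.bond_index_origin + 1)
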