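"""Hydrogen-bond networks: classical N/O contacts, weak CH···O bonds,
water coordination shells and per-conformer (altloc) networks.

Deposited X-ray models of this resolution class carry no hydrogen atoms,
so classical hydrogen bonds are identified by a donor/acceptor distance
criterion alone (default cutoff 3.2 A).  CH···O bonds get an angle, with
the hydrogen inferred geometrically on the sp2 carbon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import AtomNotFoundError
from .geometry import angle, distance, place_vinylic_hydrogen
from .model import AMINO_ACIDS, AltlocPolicy, AtomRecord, StructureModel, resolve_altlocs

logger = logging.getLogger("retgeom.hbonds")

#: distance below which a classical hydrogen bond is flagged as unusually short
SHORT_HBOND = 2.5

# --------------------------------------------------------------------------
# Donor/acceptor chemistry for the 20 amino acids, water and retinal.
# Roles: "donor", "acceptor", "both".  Backbone N donates, carbonyl O
# accepts; carboxylates are pure acceptors in the standard picture, but
# detection is pairwise over all polar atoms (see find_hbonds), so a
# protonated-carboxyl contact such as a Glu-Glu pair is still found.
# --------------------------------------------------------------------------


def _default_chemistry() -> dict[tuple[str, str], str]:
    table: dict[tuple[str, str], str] = {}
    for res in AMINO_ACIDS:
        if res != "PRO":           # proline backbone N has no H
            table[(res, "N")] = "donor"
        table[(res, "O")] = "acceptor"
        table[(res, "OXT")] = "acceptor"
    side = {
        "SER": {"OG": "both"},
        "THR": {"OG1": "both"},
        "TYR": {"OH": "both"},
        "CYS": {},                               # SG excluded: N/O chemistry only
        "ASN": {"OD1": "acceptor", "ND2": "donor"},
        "GLN": {"OE1": "acceptor", "NE2": "donor"},
        "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
        "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
        "LYS": {"NZ": "donor"},
        "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
        "HIS": {"ND1": "both", "NE2": "both"},
        "TRP": {"NE1": "donor"},
    }
    for res, atoms in side.items():
        for name, role in atoms.items():
            table[(res, name)] = role
    table[("HOH", "O")] = "both"
    # retinal: the protonated Schiff base nitrogen belongs to LYS (NZ, already
    # a donor); the polyene itself carries no N/O.
    return table


DEFAULT_CHEMISTRY = _default_chemistry()

# Same-residue polar atom pairs separated by one or two covalent bonds
# (1-2 / 1-3): never hydrogen bonds.
_INTRA_EXCLUDED: frozenset[tuple[str, frozenset[str]]] = frozenset({
    ("ASP", frozenset({"OD1", "OD2"})),
    ("GLU", frozenset({"OE1", "OE2"})),
    ("ASN", frozenset({"OD1", "ND2"})),
    ("GLN", frozenset({"OE1", "NE2"})),
    ("ARG", frozenset({"NE", "NH1"})),
    ("ARG", frozenset({"NE", "NH2"})),
    ("ARG", frozenset({"NH1", "NH2"})),
    ("HIS", frozenset({"ND1", "NE2"})),
})


@dataclass(frozen=True)
class HBond:
    """A donor/acceptor contact. ``kind`` is 'classical' or 'ch_o'."""

    donor: AtomRecord
    acceptor: AtomRecord
    distance: float
    kind: str = "classical"
    angle_dha: Optional[float] = None   # degrees at the (inferred) hydrogen; ch_o only
    conformer: str = ""                 # altloc label, "" for shared atoms
    short_flag: bool = False            # distance < SHORT_HBOND
    angle_missing: bool = False         # ch_o contact whose H could not be placed

    def __str__(self) -> str:
        extra = f" {self.angle_dha:.1f} deg" if self.angle_dha is not None else ""
        return (f"{self.donor.label()} ... {self.acceptor.label()} "
                f"{self.distance:.2f} A [{self.kind}]{extra}")


@dataclass
class CoordinationSummary:
    """Polar contacts of one water molecule within a cutoff."""

    water: AtomRecord
    partners: list[AtomRecord]
    cutoff: float

    @property
    def count(self) -> int:
        return len(self.partners)

    @property
    def complete(self) -> bool:
        """True when the water reaches the tetrahedral coordination of 4."""
        return self.count >= 4


def _altlocs_compatible(a: AtomRecord, b: AtomRecord) -> bool:
    return a.altloc == b.altloc or a.altloc == "" or b.altloc == ""


def _intra_excluded(a: AtomRecord, b: AtomRecord) -> bool:
    if a.residue_key != b.residue_key:
        return False
    if a.name == b.name:          # two conformers of the same site
        return True
    return (a.res_name, frozenset({a.name, b.name})) in _INTRA_EXCLUDED


def polar_atoms(model: StructureModel,
                chemistry: dict[tuple[str, str], str] = DEFAULT_CHEMISTRY) -> list[AtomRecord]:
    """All N/O atoms listed in the chemistry table; unknown residues are
    skipped with a log entry."""
    out = []
    warned: set[str] = set()
    for a in model.atoms:
        if a.element not in ("N", "O"):
            continue
        if (a.res_name, a.name) in chemistry:
            out.append(a)
        elif a.res_name not in AMINO_ACIDS and a.res_name not in ("HOH",):
            if a.res_name not in warned:
                logger.warning("residue %s not in chemistry table; polar atoms skipped",
                               a.res_name)
                warned.add(a.res_name)
    return out


def _role(a: AtomRecord, chemistry: dict[tuple[str, str], str]) -> str:
    return chemistry.get((a.res_name, a.name), "both")


def _orient(a: AtomRecord, b: AtomRecord, chemistry) -> tuple[AtomRecord, AtomRecord]:
    """Order a polar pair as (donor, acceptor) using the role table."""
    ra, rb = _role(a, chemistry), _role(b, chemistry)
    if ra == "donor" or rb == "acceptor":
        return a, b
    if rb == "donor" or ra == "acceptor":
        return b, a
    return a, b


def find_hbonds(model: StructureModel, cutoff: float = 3.2,
                chemistry: dict[tuple[str, str], str] = DEFAULT_CHEMISTRY,
                excluded_bonds: Iterable[frozenset[tuple]] = ()) -> list[HBond]:
    """All polar N/O···N/O contacts under ``cutoff``, sorted by distance.

    Excluded: covalently bonded and 1-3 pairs within a residue,
    conformer-incompatible pairs (altloc A vs B), and any pair whose
    site keys appear in ``excluded_bonds`` (for covalent links between
    residues, e.g. a retinal Schiff base).  Each unordered pair is
    reported once, oriented donor→acceptor by the chemistry table.
    """
    atoms = polar_atoms(model, chemistry)
    if len(atoms) < 2:
        return []
    excluded = {frozenset(pair) for pair in excluded_bonds}
    coords = np.stack([a.pos for a in atoms])
    tree = cKDTree(coords)
    bonds = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        a, b = atoms[i], atoms[j]
        if not _altlocs_compatible(a, b):
            continue
        if _intra_excluded(a, b):
            continue
        if frozenset({a.site_key, b.site_key}) in excluded:
            continue
        d = distance(a.pos, b.pos)
        don, acc = _orient(a, b, chemistry)
        conformer = don.altloc or acc.altloc
        bonds.append(HBond(donor=don, acceptor=acc, distance=d,
                           conformer=conformer, short_flag=d < SHORT_HBOND))
    bonds.sort(key=lambda h: h.distance)
    return bonds


def heavy_neighbors(model: StructureModel, atom: AtomRecord,
                    bond_cutoff: float = 1.8) -> list[AtomRecord]:
    """Covalently bonded heavy atoms, detected by distance."""
    out = []
    for b in model.atoms:
        if b.full_key == atom.full_key or b.element == "H":
            continue
        if not _altlocs_compatible(atom, b):
            continue
        if distance(atom.pos, b.pos) < bond_cutoff:
            out.append(b)
    return out


def ch_o_contacts(model: StructureModel, c_selection: Sequence[AtomRecord],
                  o_selection: Sequence[AtomRecord],
                  dist_cutoff: float = 3.5) -> list[HBond]:
    """Weak CH···O hydrogen bonds from sp2 carbons to oxygen acceptors.

    For each carbon with exactly two heavy neighbors the vinylic hydrogen
    is placed geometrically (1.0 A, in-plane external bisector) and the
    C–H···O angle at the hydrogen is reported.  Carbons whose H cannot be
    placed still yield the contact, flagged ``angle_missing``.
    """
    out = []
    for c in c_selection:
        nbrs = heavy_neighbors(model, c)
        h_pos = None
        if len(nbrs) == 2:
            try:
                h_pos = place_vinylic_hydrogen(c.pos, nbrs[0].pos, nbrs[1].pos)
            except Exception:
                logger.warning("H placement failed on %s", c.label())
        else:
            logger.warning("%s has %d heavy neighbors; expected 2 for sp2 H placement",
                           c.label(), len(nbrs))
        for o in o_selection:
            d = distance(c.pos, o.pos)
            if d > dist_cutoff or not _altlocs_compatible(c, o):
                continue
            if h_pos is not None:
                ang = angle(c.pos, h_pos, o.pos)
                out.append(HBond(donor=c, acceptor=o, distance=d, kind="ch_o",
                                 angle_dha=ang, conformer=c.altloc or o.altloc,
                                 short_flag=d < SHORT_HBOND))
            else:
                out.append(HBond(donor=c, acceptor=o, distance=d, kind="ch_o",
                                 angle_dha=None, angle_missing=True,
                                 conformer=c.altloc or o.altloc,
                                 short_flag=d < SHORT_HBOND))
    out.sort(key=lambda h: h.distance)
    return out


def water_coordination(model: StructureModel, res_seq: int,
                       chain_id: Optional[str] = None,
                       cutoff: float = 3.2) -> CoordinationSummary:
    """Polar heavy-atom partners of one water molecule.

    ``complete`` is True when at least four partners lie within the
    cutoff — the tetrahedral coordination of bulk water.  Buried waters
    in proton-transfer paths typically fall short of it.
    """
    waters = [a for a in model.atoms
              if a.is_water and a.res_seq == res_seq
              and (chain_id is None or a.chain_id == chain_id)]
    waters = resolve_altlocs(waters, AltlocPolicy.HIGHEST_OCCUPANCY)
    if not waters:
        raise AtomNotFoundError(f"water {res_seq} not found"
                                + (f" in chain {chain_id}" if chain_id else ""))
    w = waters[0]
    partners: dict[tuple, AtomRecord] = {}
    for a in model.atoms:
        if a.element not in ("N", "O") or a.residue_key == w.residue_key:
            continue
        if not _altlocs_compatible(w, a):
            continue
        if distance(w.pos, a.pos) <= cutoff:
            k = a.site_key
            if k not in partners or a.occupancy > partners[k].occupancy:
                partners[k] = a
    plist = sorted(partners.values(), key=lambda a: distance(w.pos, a.pos))
    return CoordinationSummary(water=w, partners=plist, cutoff=cutoff)


@dataclass
class ConformerNetwork:
    """Hydrogen bonds visible in one alternate conformation."""

    label: str
    occupancy: float
    bonds: list[HBond] = field(default_factory=list)


def conformer_networks(model: StructureModel, cutoff: float = 3.2,
                       chemistry: dict[tuple[str, str], str] = DEFAULT_CHEMISTRY,
                       occupancy_spread_warn: float = 0.05) -> dict[str, ConformerNetwork]:
    """One hydrogen-bond network per altloc label.

    Network L is computed on the submodel of blank-altloc atoms (shared
    by all conformations) plus label-L atoms.  The network occupancy is
    the mean occupancy of the label's member atoms; an inconsistent
    group (spread above ``occupancy_spread_warn``) is logged.
    A model without altlocs yields a single network under the blank label.
    """
    labels = sorted({a.altloc for a in model.atoms if a.altloc})
    if not labels:
        occ = float(np.mean([a.occupancy for a in model.atoms])) if model.atoms else 1.0
        return {"": ConformerNetwork(label="", occupancy=occ,
                                     bonds=find_hbonds(model, cutoff, chemistry))}
    out = {}
    for lab in labels:
        members = [a for a in model.atoms if a.altloc == lab]
        occs = [a.occupancy for a in members]
        spread = max(occs) - min(occs)
        if spread > occupancy_spread_warn:
            logger.warning("altloc %s occupancies span %.2f", lab, spread)
        sub = model.with_atoms([a for a in model.atoms if a.altloc in ("", lab)])
        out[lab] = ConformerNetwork(label=lab, occupancy=float(np.mean(occs)),
                                    bonds=find_hbonds(sub, cutoff, chemistry))
    return out
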