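"""In-memory coordinate model: atoms, structures and atom selections.

The unit every analysis consumes is :class:`StructureModel`, an ordered
list of :class:`AtomRecord` plus cell metadata.  Alternate conformations
(altlocs) are first-class: each conformer of an atom is its own record
with its own occupancy and B factor, exactly as deposited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

# Canonical 3-letter codes of the 20 amino acids.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_RES_NAME = "HOH"
RETINAL_RES_NAME = "RET"


@dataclass(frozen=True)
class AtomRecord:
    """One atom (one conformer of one atom site) from a coordinate file."""

    serial: int
    name: str
    altloc: str           # single letter, or "" when the atom has one conformer
    res_name: str
    chain_id: str
    res_seq: int          # author numbering, as deposited
    icode: str            # insertion code, or ""
    pos: np.ndarray       # shape (3,), angstrom
    occupancy: float
    b_iso: float          # angstrom^2
    element: str
    u_aniso: Optional[np.ndarray] = None  # symmetric 3x3, angstrom^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        if self.pos.shape != (3,):
            raise ValueError(f"pos must be a 3-vector, got shape {self.pos.shape}")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("atom position must be finite")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0 or not math.isfinite(self.b_iso):
            raise ValueError(f"b_iso must be finite and >= 0, got {self.b_iso}")
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if self.u_aniso is not None:
            u = np.asarray(self.u_aniso, dtype=float)
            if u.shape != (3, 3):
                raise ValueError("u_aniso must be 3x3")
            object.__setattr__(self, "u_aniso", u)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, res_seq, icode): identifies a residue."""
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """(chain, res_seq, icode, name): identifies an atom site across conformers."""
        return (self.chain_id, self.res_seq, self.icode, self.name)

    @property
    def full_key(self) -> tuple[str, int, str, str, str]:
        return (self.chain_id, self.res_seq, self.icode, self.name, self.altloc)

    @property
    def is_water(self) -> bool:
        return self.res_name == WATER_RES_NAME

    @property
    def is_amino(self) -> bool:
        return self.res_name in AMINO_ACIDS

    def label(self) -> str:
        """Human-readable identifier, e.g. ``A/LYS216/NZ`` or ``A/HOH402/O(B)``."""
        alt = f"({self.altloc})" if self.altloc else ""
        return f"{self.chain_id}/{self.res_name}{self.res_seq}{self.icode.strip()}/{self.name}{alt}"

    def moved_to(self, pos: np.ndarray) -> "AtomRecord":
        return replace(self, pos=np.asarray(pos, dtype=float))


@dataclass
class StructureModel:
    """Ordered collection of atoms plus crystallographic metadata."""

    atoms: list[AtomRecord] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    space_group: str = "P 1"
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            k = a.full_key
            if k in seen:
                raise ValueError(f"duplicate atom {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """(N, 3) array of positions in file order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.pos for a in self.atoms])

    def with_atoms(self, atoms: Iterable[AtomRecord]) -> "StructureModel":
        return StructureModel(atoms=list(atoms), cell=self.cell,
                              space_group=self.space_group, label=self.label)

    def find_atoms(self, *, chain_id: Optional[str] = None, res_seq: Optional[int] = None,
                   res_name: Optional[str] = None, name: Optional[str] = None) -> list[AtomRecord]:
        """All atom records (every conformer) matching the given fields."""
        out = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if res_seq is not None and a.res_seq != res_seq:
                continue
            if res_name is not None and a.res_name != res_name:
                continue
            if name is not None and a.name != name:
                continue
            out.append(a)
        return out

    def find_atom(self, **kwargs) -> AtomRecord:
        """The single best atom matching the fields; altloc ties resolved by
        highest occupancy, then altloc letter ascending."""
        from .errors import AtomNotFoundError

        hits = self.find_atoms(**kwargs)
        if not hits:
            raise AtomNotFoundError(f"no atom matching {kwargs}")
        return max(hits, key=lambda a: (a.occupancy, _neg_ord(a.altloc)))


def _neg_ord(altloc: str) -> float:
    # blank sorts first among equals, then "A" beats "B"
    return -ord(altloc) if altloc else 1.0


class AltlocPolicy(str, Enum):
    """How alternate conformations are resolved in a selection."""

    ALL = "all"
    BLANK_OR_LABEL = "blank_or_label"
    HIGHEST_OCCUPANCY = "highest_occupancy"


@dataclass
class Selection:
    """Declarative atom filter.  At least one criterion must be set."""

    chain_id: Optional[str] = None
    res_seq: Optional[int] = None
    res_name: Optional[str] = None
    atom_names: Optional[frozenset[str]] = None
    altloc_policy: AltlocPolicy = AltlocPolicy.HIGHEST_OCCUPANCY
    altloc_label: str = ""   # used by BLANK_OR_LABEL

    def __post_init__(self) -> None:
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)
        self.altloc_policy = AltlocPolicy(self.altloc_policy)
        if (self.chain_id is None and self.res_seq is None and self.res_name is None
                and self.atom_names is None):
            raise ValueError("Selection requires at least one criterion")

    def matches(self, a: AtomRecord) -> bool:
        if self.chain_id is not None and a.chain_id != self.chain_id:
            return False
        if self.res_seq is not None and a.res_seq != self.res_seq:
            return False
        if self.res_name is not None and a.res_name != self.res_name:
            return False
        if self.atom_names is not None and a.name not in self.atom_names:
            return False
        return True


def resolve_altlocs(atoms: Sequence[AtomRecord], policy: AltlocPolicy,
                    label: str = "") -> list[AtomRecord]:
    """Apply an altloc policy to a list of records, preserving order.

    ``HIGHEST_OCCUPANCY`` keeps one conformer per atom site — ties broken
    by altloc letter ascending, so "A" wins a 0.5/0.5 split.
    """
    if policy == AltlocPolicy.ALL:
        return list(atoms)
    if policy == AltlocPolicy.BLANK_OR_LABEL:
        return [a for a in atoms if a.altloc in ("", label)]
    # HIGHEST_OCCUPANCY
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        k = a.site_key
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, _neg_ord(a.altloc)) > (b.occupancy, _neg_ord(b.altloc)):
                best[k] = a
    return [best[k] for k in order]
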