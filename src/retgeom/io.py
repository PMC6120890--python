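"""Reading and writing macromolecular coordinate files.

Parsing goes through gemmi, which handles both the PDB fixed-column
dialect and mmCIF ``atom_site`` records; the result is flattened into the
package's own :class:`~retgeom.model.StructureModel` with faithful altloc,
occupancy, B-factor and anisotropic-tensor handling.  Output is PDB v3.3
fixed columns (via gemmi), re-readable by :func:`read_structure`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import gemmi

from .errors import FormattingError, ParseError, UnsupportedFormatError
from .model import (
    AMINO_ACIDS,
    AtomRecord,
    Selection,
    StructureModel,
    resolve_altlocs,
)

PathOrText = Union[str, os.PathLike]


@dataclass
class ComponentConfig:
    """How HETATM residue codes map onto composition categories.

    Everything that is neither water, retinal nor an amino acid counts as
    lipid by default — the deposits carry monoolein/squalane fragments
    under assorted codes.
    """

    retinal_codes: frozenset[str] = frozenset({"RET"})
    water_codes: frozenset[str] = frozenset({"HOH", "WAT", "DOD"})
    water_aliases: dict[str, tuple[str, int]] = field(default_factory=dict)
    # e.g. {"Wat402": ("A", 402)} when numbering differs between deposits


DEFAULT_COMPONENT_CONFIG = ComponentConfig()


def _looks_like_path(source: PathOrText) -> bool:
    if isinstance(source, os.PathLike):
        return True
    return "\n" not in source and os.path.exists(source)


def _from_gemmi(st: gemmi.Structure, label: str) -> StructureModel:
    cell = st.cell
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        return StructureModel(atoms=[], label=label)
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                altloc = at.altloc if at.altloc and at.altloc != "\x00" else ""
                u = None
                if at.aniso.nonzero():
                    a = at.aniso
                    u = np.array([[a.u11, a.u12, a.u13],
                                  [a.u12, a.u22, a.u23],
                                  [a.u13, a.u23, a.u33]], dtype=float)
                atoms.append(AtomRecord(
                    serial=at.serial,
                    name=at.name,
                    altloc=altloc,
                    res_name=res.name,
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=round(float(at.occ), 4),
                    b_iso=round(float(at.b_iso), 4),
                    element=at.element.name,
                    u_aniso=u,
                ))
    return StructureModel(
        atoms=atoms,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        space_group=st.spacegroup_hm or "P 1",
        label=label,
    )


def read_structure(source: PathOrText, format: str = "pdb") -> StructureModel:
    """Parse a PDB or mmCIF file (path or raw text) into a StructureModel.

    Parameters
    ----------
    source:
        A filesystem path, or the file content itself as a string.
    format:
        ``"pdb"`` or ``"mmcif"``.

    Raises
    ------
    UnsupportedFormatError
        For an unknown format tag.
    ParseError
        When the text does not parse under the requested dialect; for PDB
        input the offending line number is named when identifiable.
    """
    if format not in ("pdb", "mmcif"):
        raise UnsupportedFormatError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")
    is_path = _looks_like_path(source)
    label = os.fspath(source) if is_path else ""
    if is_path:
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    if format == "pdb":
        _validate_pdb_lines(text)
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
            raise ParseError(f"PDB parse failed: {exc}") from exc
    else:
        try:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"mmCIF parse failed: {exc}") from exc
    return _from_gemmi(st, label)


def _validate_pdb_lines(text: str) -> None:
    """Reject malformed fixed-column ATOM/HETATM lines, naming the line."""
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ParseError(f"line {i}: ATOM/HETATM record shorter than coordinate columns")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"line {i}: malformed {what} coordinate field {fieldtxt!r}"
                    ) from None


def write_structure(model: StructureModel, path: PathOrText, format: str = "pdb") -> None:
    """Write a model as PDB v3.3 fixed columns.

    Raises :class:`FormattingError` when an atom name or residue code does
    not fit its fixed-column field.
    """
    if format != "pdb":
        raise UnsupportedFormatError(f"write_structure supports only 'pdb', got {format!r}")
    with open(path, "w") as fh:
        fh.write(structure_to_pdb_string(model))


def structure_to_pdb_string(model: StructureModel) -> str:
    for a in model.atoms:
        if len(a.name) > 4:
            raise FormattingError(f"atom name {a.name!r} exceeds 4 characters")
        if len(a.res_name) > 3:
            raise FormattingError(f"residue name {a.res_name!r} exceeds 3 characters")
        if len(a.chain_id) > 1:
            raise FormattingError(f"chain id {a.chain_id!r} exceeds 1 character")
        if not (-999 <= a.res_seq <= 9999):
            raise FormattingError(f"residue number {a.res_seq} does not fit PDB columns")
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell)
    st.spacegroup_hm = model.space_group
    gm = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple, gemmi.Residue] = {}
    serial = 0
    for a in model.atoms:
        ch = chain_map.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id or "A")
            chain_map[a.chain_id] = ch
        rk = (a.chain_id, a.res_seq, a.icode, a.res_name)
        res = res_map.get(rk)
        if res is None:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            res.het_flag = "A" if a.res_name in AMINO_ACIDS else "H"
            res_map[rk] = res
        at = gemmi.Atom()
        at.name = a.name
        at.altloc = a.altloc or "\x00"
        at.pos = gemmi.Position(*a.pos)
        at.occ = a.occupancy
        at.b_iso = a.b_iso
        at.element = gemmi.Element(a.element)
        serial += 1
        at.serial = serial
        if a.u_aniso is not None:
            u = a.u_aniso
            at.aniso = gemmi.SMat33f(u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2])
        res.add_atom(at)
    for rk, res in res_map.items():
        chain_map[rk[0]].add_residue(res)
    for ch in chain_map.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(seqres_records=False, ssbond_records=False,
                                                    link_records=False, cispep_records=False))


def select_atoms(model: StructureModel, sel: Selection) -> list[AtomRecord]:
    """Atoms matching every set criterion, altlocs resolved per policy.

    Order follows the model; an empty result is valid.
    """
    hits = [a for a in model.atoms if sel.matches(a)]
    return resolve_altlocs(hits, sel.altloc_policy, sel.altloc_label)


def count_components(model: StructureModel,
                     config: ComponentConfig = DEFAULT_COMPONENT_CONFIG) -> dict[str, int]:
    """Composition summary: distinct residues per category plus protein atom count.

    Counts distinct ``(chain, res_seq, icode)`` per category; a residue
    modeled in two conformations still counts once.  ``protein_atoms``
    counts atom records in amino-acid residues including every altloc.
    """
    amino: set[tuple] = set()
    waters: set[tuple] = set()
    retinals: set[tuple] = set()
    lipids: set[tuple] = set()
    protein_atoms = 0
    for a in model.atoms:
        key = a.residue_key
        if a.res_name in AMINO_ACIDS:
            amino.add(key)
            protein_atoms += 1
        elif a.res_name in config.water_codes:
            waters.add(key)
        elif a.res_name in config.retinal_codes:
            retinals.add(key)
        else:
            lipids.add(key)
    return {
        "amino_residues": len(amino),
        "retinal": len(retinals),
        "lipids": len(lipids),
        "waters": len(waters),
        "protein_atoms": protein_atoms,
    }
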