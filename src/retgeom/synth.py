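"""Synthetic-structure and synthetic-data generators.

Everything the analysis pipeline consumes can be generated here without
external downloads: polyene chains with exactly prescribed torsions
(internal-coordinate chain building), donor/acceptor clusters at exact
separations including paired alternate conformations, replicate
ensembles with Gaussian coordinate noise, and radiation-damage dose
series following single-exponential kinetics with sentinel B-factor
inflation.  All randomness flows from one explicit seed; identical
seeds give byte-identical fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .damage import DEFAULT_SENTINELS, DoseObservation
from .errors import ConstructionError
from .helicity import DEFAULT_PATH, PolyeneDefinition, torsion_from_helicity
from .model import AtomRecord, StructureModel

# ---------------------------------------------------------------------------
# Internal-coordinate chain building
# ---------------------------------------------------------------------------


def place_by_internal_coords(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                             bond: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that |d−c| = bond, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion (degrees) — the standard sequential
    (NeRF) construction."""
    theta = math.radians(bond_angle)
    phi = math.radians(torsion)
    d_local = bond * np.array([-math.cos(theta),
                               math.sin(theta) * math.cos(phi),
                               math.sin(theta) * math.sin(phi)])
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ConstructionError("collinear preceding atoms; torsion frame undefined")
    n_hat = n / nn
    m_hat = np.cross(n_hat, bc_hat)
    frame = np.column_stack([bc_hat, m_hat, n_hat])
    return c + frame @ d_local


@dataclass(frozen=True)
class PolyeneSpec:
    """A conjugated chain with prescribed per-bond torsions.

    With the default ``n_atoms = 14`` the chain is named like the retinal
    chromophore path (C4…C15 in a RET residue, then NZ and CE of the
    linking lysine), so it feeds straight into the helicity analysis.
    Bond length 1.45 A and angle 120 deg are typical of a conjugated
    chain; they do not affect torsion recovery.
    """

    n_atoms: int = 14
    bond_length: float = 1.45
    bond_angle: float = 120.0
    torsions: tuple[float, ...] = tuple([180.0] * 11)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.n_atoms < 4:
            raise ConstructionError("polyene needs at least 4 atoms")
        if len(self.torsions) != self.n_atoms - 3:
            raise ConstructionError(
                f"need {self.n_atoms - 3} torsions for {self.n_atoms} atoms, "
                f"got {len(self.torsions)}")
        for t in self.torsions:
            if not (-180.0 < t <= 180.0):
                raise ConstructionError(f"torsion {t} outside (-180, 180]")

    def definition(self) -> PolyeneDefinition:
        """The matching helicity path definition."""
        if self.n_atoms == 14:
            return PolyeneDefinition()
        return PolyeneDefinition(path=tuple(f"C{i + 1}" for i in range(self.n_atoms)))


def generate_polyene(spec: PolyeneSpec = PolyeneSpec()) -> StructureModel:
    """Build a polyene chain by sequential internal-coordinate placement.

    Recovered torsions equal the specification to well under 1e-6 deg.
    """
    n = spec.n_atoms
    d, ang = spec.bond_length, spec.bond_angle
    coords = [np.zeros(3), np.array([d, 0.0, 0.0])]
    theta = math.radians(ang)
    coords.append(coords[1] + d * np.array([-math.cos(theta), math.sin(theta), 0.0]))
    for i in range(3, n):
        coords.append(place_by_internal_coords(coords[i - 3], coords[i - 2], coords[i - 1],
                                               d, ang, spec.torsions[i - 3]))
    if n == 14:
        names = list(DEFAULT_PATH)
        res_names = ["RET"] * 12 + ["LYS"] * 2
        res_seqs = [300] * 12 + [216] * 2
    else:
        names = [f"C{i + 1}" for i in range(n)]
        res_names = ["RET"] * n
        res_seqs = [300] * n
    atoms = []
    for i, (pos, name) in enumerate(zip(coords, names)):
        atoms.append(AtomRecord(serial=i + 1, name=name, altloc="",
                                res_name=res_names[i], chain_id=spec.chain_id,
                                res_seq=res_seqs[i], icode="", pos=pos,
                                occupancy=1.0, b_iso=10.0,
                                element=name[0]))
    return StructureModel(atoms=atoms, label="synthetic-polyene")


def polyene_from_helicities(etas: Sequence[float],
                            defn: PolyeneDefinition = PolyeneDefinition()) -> StructureModel:
    """Polyene whose per-bond helicities equal ``etas`` under ``defn``'s parity."""
    parities = defn.bond_parities()
    if len(etas) != len(parities):
        raise ConstructionError(f"need {len(parities)} helicities, got {len(etas)}")
    torsions = tuple(torsion_from_helicity(e, n) for e, n in zip(etas, parities))
    return generate_polyene(PolyeneSpec(n_atoms=len(defn.path), torsions=torsions))


# Helicity profiles (degrees, bond order C5-C6 ... C15-NZ) used as synthetic
# stand-ins for the deposited chromophores, which cannot be downloaded here.
# SYNTHETIC_REFERENCE_ETAS mimics the earlier 1.55-A ground-state model with
# its large -10 deg twist at C5-C6; SYNTHETIC_GROUND_STATE_ETAS mimics the
# low-damage chromophore: nearly planar C5-C6 (1.5 deg) and deviations above
# 5 deg from the reference at C5-C6, C11-C12 and C14-C15 only.
SYNTHETIC_REFERENCE_ETAS = (-10.0, 2.0, -1.0, 3.0, -2.0, 4.0, -3.0, 2.0, -4.0, 0.5, 5.0)
SYNTHETIC_GROUND_STATE_ETAS = (1.5, 3.0, -2.0, 4.0, -3.0, 2.0, -12.0, 0.0, -2.0, 8.0, 7.0)


def synthetic_reference_chromophore() -> StructureModel:
    """Synthetic stand-in for the earlier-model retinal chromophore
    (C5-C6 helicity −10 deg).  Not deposited coordinates."""
    m = polyene_from_helicities(SYNTHETIC_REFERENCE_ETAS)
    m.label = "synthetic-reference-chromophore"
    return m


def synthetic_ground_state_chromophore() -> StructureModel:
    """Synthetic stand-in for a low-damage ground-state chromophore
    (C5-C6 helicity 1.5 deg).  Not deposited coordinates."""
    m = polyene_from_helicities(SYNTHETIC_GROUND_STATE_ETAS)
    m.label = "synthetic-ground-state-chromophore"
    return m


# ---------------------------------------------------------------------------
# Hydrogen-bond clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairSpec:
    """One donor/acceptor pair at an exact separation.

    Atoms are identified as (res_name, res_seq, atom_name); an atom
    identity may recur across pairs, in which case its first placement
    is reused and the partner is placed at the requested distance.
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    distance: float
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.distance <= 1.5:
            raise ConstructionError(f"pair distance {self.distance} must exceed 1.5 A")


def generate_hbond_cluster(pairs: Sequence[PairSpec], chain_id: str = "A") -> StructureModel:
    """Place donor/acceptor atoms at exact requested separations.

    Pairs are laid out on separate rows 8 A apart; partners of an
    already-placed atom go along a direction unique to the pair so
    clusters sharing atoms stay consistent.  Conflicting re-placements
    raise :class:`ConstructionError`.
    """
    placed: dict[tuple[str, int, str, str], np.ndarray] = {}
    meta: dict[tuple[str, int, str, str], PairSpec] = {}

    def key(ident, altloc):
        return (ident[0], ident[1], ident[2], altloc)

    for j, p in enumerate(pairs):
        dk, ak = key(p.donor, p.altloc), key(p.acceptor, p.altloc)
        angle = math.radians(37.0 * j)             # unique direction per pair
        direction = np.array([math.cos(angle), 0.0, math.sin(angle)])
        if dk in placed and ak in placed:
            have = float(np.linalg.norm(placed[dk] - placed[ak]))
            if abs(have - p.distance) > 1e-9:
                raise ConstructionError(
                    f"pair {p.donor}-{p.acceptor} ({p.altloc or 'blank'}) already placed "
                    f"at {have:.3f} A, requested {p.distance:.3f} A")
            continue
        if dk not in placed and ak not in placed:
            placed[dk] = np.array([0.0, 8.0 * j, 0.0])
            meta[dk] = p
        anchor, new = (dk, ak) if dk in placed else (ak, dk)
        placed[new] = placed[anchor] + direction * p.distance
        meta[new] = p
        meta.setdefault(anchor, p)

    atoms = []
    for i, (k, pos) in enumerate(placed.items()):
        res_name, res_seq, name, altloc = k
        atoms.append(AtomRecord(serial=i + 1, name=name, altloc=altloc,
                                res_name=res_name, chain_id=chain_id, res_seq=res_seq,
                                icode="", pos=pos, occupancy=meta[k].occupancy,
                                b_iso=15.0, element=name[0]))
    return StructureModel(atoms=atoms, label="synthetic-hbond-cluster")


# ---------------------------------------------------------------------------
# Replicate ensembles
# ---------------------------------------------------------------------------


def perturb_replicates(model: StructureModel, sigma: float, n: int,
                       seed: int = 0) -> list[StructureModel]:
    """n copies of ``model`` with independent N(0, sigma^2) noise per
    coordinate axis — an idealization of independently refined
    isomorphous replicates."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        noise = rng.normal(0.0, sigma, size=(len(model.atoms), 3)) if sigma > 0 \
            else np.zeros((len(model.atoms), 3))
        atoms = [a.moved_to(a.pos + noise[j]) for j, a in enumerate(model.atoms)]
        rep = model.with_atoms(atoms)
        rep.label = f"{model.label or 'model'}-rep{i + 1}"
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# Damage dose series
# ---------------------------------------------------------------------------

# Experimental dose schedule emulated by default: twelve successive
# low-dose datasets from 0.01 to 0.23 MGy, then four more datasets each
# preceded by a deliberate 0.22 MGy burn.
DEFAULT_DOSE_SCHEDULE: tuple[float, ...] = tuple(
    round(0.01 + 0.02 * i, 2) for i in range(12)) + (0.47, 0.71, 0.95, 1.19)


@dataclass(frozen=True)
class DoseSeriesSpec:
    """True kinetics and noise for a synthetic damage dose series.

    Defaults: the 16-dataset dose schedule above; saturation kinetics
    A = 0.6, tau = 0.5 MGy giving a well-resolved curve over that
    schedule; calibration slope k = 6.7 fraction/A^2; q refinable only
    above 0.15 MGy (below that only the sentinel ⟨ΔB⟩ proxy is
    observed, as in low-dose practice).
    """

    doses: tuple[float, ...] = DEFAULT_DOSE_SCHEDULE
    amplitude: float = 0.6
    dose_constant: float = 0.5     # MGy
    k: float = 6.7                 # fraction per A^2
    sigma_q: float = 0.02
    sigma_b: float = 0.003         # A^2, noise on delta_b
    q_refinable_above: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses):
            raise ConstructionError("doses must be non-negative")
        if list(self.doses) != sorted(self.doses):
            raise ConstructionError("doses must be ascending")
        if self.sigma_q < 0 or self.sigma_b < 0:
            raise ConstructionError("noise scales must be >= 0")
        if not (0 < self.amplitude <= 1) or self.dose_constant <= 0:
            raise ConstructionError("need 0 < amplitude <= 1 and dose_constant > 0")

    def q_true(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return self.amplitude * (1.0 - np.exp(-d / self.dose_constant))


def dose_series_spec_cryo_15k(**overrides) -> DoseSeriesSpec:
    """Kinetics emulating the strongly damage-suppressed 15 K condition:
    5% damage accumulates by 0.15 MGy."""
    tau = 0.15 / -math.log1p(-0.05 / 0.6)
    return DoseSeriesSpec(amplitude=0.6, dose_constant=tau, **overrides)


def dose_series_spec_cryo_100k(**overrides) -> DoseSeriesSpec:
    """Kinetics emulating the 100 K condition: 5% damage by 0.08 MGy."""
    tau = 0.08 / -math.log1p(-0.05 / 0.6)
    return DoseSeriesSpec(amplitude=0.6, dose_constant=tau, **overrides)


def _sentinel_site_model(b_iso: float, label: str) -> StructureModel:
    """Minimal model carrying the four damage-sentinel atoms."""
    specs = DEFAULT_SENTINELS
    positions = [np.array([0.0, 0.0, 0.0]), np.array([2.2, 0.0, 0.0]),
                 np.array([0.0, 3.0, 0.0]), np.array([2.0, 2.0, 1.0])]
    atoms = []
    for i, (s, pos) in enumerate(zip(specs, positions)):
        atoms.append(AtomRecord(serial=i + 1, name=s.name, altloc="",
                                res_name=s.res_name, chain_id="A", res_seq=s.res_seq,
                                icode="", pos=pos, occupancy=1.0, b_iso=b_iso,
                                element=s.name[0]))
    return StructureModel(atoms=atoms, label=label)


@dataclass
class DoseSeriesResult:
    observations: list[DoseObservation]
    reference_model: Optional[StructureModel] = None
    dosed_models: list[StructureModel] = field(default_factory=list)


def generate_dose_series(spec: DoseSeriesSpec = DoseSeriesSpec(),
                         with_models: bool = False) -> DoseSeriesResult:
    """Synthesize a damage dose series from known kinetics.

    Per dose D: q_true = A(1 − exp(−D/τ)); the observed q is q_true plus
    N(0, σ_q²) noise clipped to [0, 1] (reported only above the
    refinability threshold), and the observed ⟨ΔB⟩ is q_true/k plus
    N(0, σ_b²) noise.  With ``with_models`` the series also carries a
    reference model and per-dose copies whose sentinel B factors are
    inflated by exactly q_true/k (plus the same noise), so the
    structural ⟨ΔB⟩ route reproduces the tabulated one.
    """
    rng = np.random.default_rng(spec.seed)
    obs = []
    ref = _sentinel_site_model(10.0, "synthetic-dose-reference") if with_models else None
    dosed_models = []
    for i, dose in enumerate(spec.doses):
        q_true = float(spec.q_true(dose))
        q_obs = float(np.clip(q_true + rng.normal(0.0, spec.sigma_q), 0.0, 1.0)) \
            if spec.sigma_q > 0 else q_true
        db_true = q_true / spec.k
        db_obs = db_true + (float(rng.normal(0.0, spec.sigma_b)) if spec.sigma_b > 0 else 0.0)
        q_out = q_obs if dose > spec.q_refinable_above else None
        obs.append(DoseObservation(dataset=f"ds{i + 1:02d}", dose=dose,
                                   q=q_out, delta_b=db_obs))
        if with_models:
            m = _sentinel_site_model(10.0, f"synthetic-dose-{dose:.2f}MGy")
            m.atoms = [replace(a, b_iso=a.b_iso + db_obs) for a in m.atoms]
            dosed_models.append(m)
    return DoseSeriesResult(observations=obs, reference_model=ref,
                            dosed_models=dosed_models)
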