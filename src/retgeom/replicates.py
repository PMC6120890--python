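"""Replicate-based uncertainty for geometric quantities.

Independently refined isomorphous structures act as replicates: a
distance is reported as the mean over the ensemble with a sample
standard deviation, and a difference from a reference value counts as
significant only when it exceeds k standard deviations (k = 4 by
default — a deliberately conservative rule for sub-0.1 A claims).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AtomNotFoundError, InsufficientReplicatesError
from .geometry import distance, rmsd_common_calpha
from .model import StructureModel


@dataclass(frozen=True)
class AtomSpec:
    """Identifies one atom site: chain (optional), residue number, atom name."""

    res_seq: int
    name: str
    chain_id: Optional[str] = None
    res_name: Optional[str] = None

    @classmethod
    def parse(cls, text: str) -> "AtomSpec":
        """Parse ``"A/216/NZ"`` or ``"216/NZ"``."""
        parts = text.split("/")
        if len(parts) == 3:
            return cls(chain_id=parts[0] or None, res_seq=int(parts[1]), name=parts[2])
        if len(parts) == 2:
            return cls(res_seq=int(parts[0]), name=parts[1])
        raise ValueError(f"cannot parse atom spec {text!r}; expected chain/resseq/name")

    def resolve(self, model: StructureModel):
        kwargs = {"res_seq": self.res_seq, "name": self.name}
        if self.chain_id is not None:
            kwargs["chain_id"] = self.chain_id
        if self.res_name is not None:
            kwargs["res_name"] = self.res_name
        return model.find_atom(**kwargs)


@dataclass
class DistanceEstimate:
    """A distance averaged over replicate structures."""

    pair: tuple[AtomSpec, AtomSpec]
    values: list[float]          # per-replicate, angstrom

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample SD (n−1); 0.0 for a single replicate."""
        if self.n < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))

    def __str__(self) -> str:
        return f"{self.mean:.2f} +/- {self.sd:.2f} A (n={self.n})"


@dataclass(frozen=True)
class SignificanceReport:
    """Is a difference from a reference value outside replicate noise?"""

    estimate: DistanceEstimate
    reference: float
    k: float

    @property
    def difference(self) -> float:
        return self.estimate.mean - self.reference

    @property
    def significant(self) -> bool:
        """Strict inequality: |difference| must exceed k·sd, not merely equal it."""
        return abs(self.difference) > self.k * self.estimate.sd


def replicate_distance(models: Sequence[StructureModel],
                       a: AtomSpec, b: AtomSpec) -> DistanceEstimate:
    """Per-replicate distance between two atom sites, with mean and sample SD.

    Every model must resolve both atoms; a missing atom names the
    offending model in the error.
    """
    values = []
    for m in models:
        try:
            pa, pb = a.resolve(m), b.resolve(m)
        except AtomNotFoundError as exc:
            raise AtomNotFoundError(f"model {m.label or '<unnamed>'}: {exc}") from exc
        values.append(distance(pa.pos, pb.pos))
    return DistanceEstimate(pair=(a, b), values=values)


def significant_difference(est: DistanceEstimate, reference: float,
                           k: float = 4.0) -> SignificanceReport:
    """Apply the k-sigma significance rule to a replicate estimate."""
    if est.n < 2:
        raise InsufficientReplicatesError(
            f"significance needs >= 2 replicates, got {est.n}")
    return SignificanceReport(estimate=est, reference=reference, k=k)


def pairwise_calpha_rmsd(models: Sequence[StructureModel]) -> np.ndarray:
    """Symmetric matrix of common-C-alpha RMSDs over an ensemble."""
    if len(models) < 2:
        raise InsufficientReplicatesError("need >= 2 models for pairwise RMSD")
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, _ = rmsd_common_calpha(models[i], models[j])
            mat[i, j] = mat[j, i] = r
    return mat
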