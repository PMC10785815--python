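"""Coarse-grained particle system containers.

A :class:`CGTopology` is a flat bead table (species, charge, radius, position,
chain id, fixed flag) plus harmonic bond and angle lists.  It is the single
in-memory representation shared by the builder, the force field, the
integrator and the analyses.  Positions are stored in nm, charges in
elementary charges, energies implied in k_BT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd


class Species(IntEnum):
    CORE = 0       # fixed bead of the rigid 6HB template (2 bp of duplex)
    SS_BEAD = 1    # single-stranded brush bead (3 nt)
    DS_BEAD = 2    # double-stranded brush bead (3 bp)
    PRECURSOR = 3  # cationic TMAPS/TEOS silica precursor
    ION_MONO = 4   # explicit monovalent ion
    ION_DI = 5     # explicit divalent ion (Mg2+)


#: Species regarded as part of the DNA template (targets of the short-range
#: precursor attraction and of the electrostatic surface scan).
DNA_SPECIES = (Species.CORE, Species.SS_BEAD, Species.DS_BEAD)

#: Brush species only.
BRUSH_SPECIES = (Species.SS_BEAD, Species.DS_BEAD)


class Boundary(IntEnum):
    PERIODIC = 0
    REFLECTING = 1


@dataclass(frozen=True)
class BoxSpec:
    """Orthorhombic box with a per-axis boundary condition.

    The default simulation geometry is reflecting in x and y (radial walls,
    conserving precursor count) and periodic in z (the bundle axis), which
    approximates an infinite bundle segment.
    """

    lengths: np.ndarray
    boundary: np.ndarray  # Boundary value per axis

    def __init__(self, lengths: Sequence[float], boundary: Optional[Sequence[int]] = None):
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (3,) or np.any(lengths <= 0):
            raise ValueError("box needs three positive edge lengths")
        if boundary is None:
            boundary = [Boundary.REFLECTING, Boundary.REFLECTING, Boundary.PERIODIC]
        boundary = np.asarray([int(b) for b in boundary], dtype=np.int64)
        if boundary.shape != (3,):
            raise ValueError("boundary needs three entries")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "boundary", boundary)

    @property
    def periodic(self) -> np.ndarray:
        return self.boundary == int(Boundary.PERIODIC)

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def volume_litres(self) -> float:
        return self.volume_nm3 * 1e-24

    def center(self) -> np.ndarray:
        return self.lengths / 2.0

    def contains(self, positions: np.ndarray, tol: float = 1e-9) -> bool:
        p = np.atleast_2d(positions)
        return bool(np.all(p >= -tol) and np.all(p <= self.lengths + tol))


@dataclass
class CGTopology:
    """Bead table plus bonded terms; grown in place by the builder."""

    species: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    charge: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    radius: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    position: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=float))
    chain_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fixed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    bond_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bond_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bond_r0: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    bond_k: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    angle_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    angle_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    angle_kappa: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    @property
    def n_beads(self) -> int:
        return len(self.species)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_i)

    @property
    def n_angles(self) -> int:
        return len(self.angle_i)

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_beads else 0

    def species_counts(self) -> Dict[Species, int]:
        return {sp: int(np.sum(self.species == int(sp))) for sp in Species}

    def mask(self, *species: Species) -> np.ndarray:
        out = np.zeros(self.n_beads, dtype=bool)
        for sp in species:
            out |= self.species == int(sp)
        return out

    def add_beads(
        self,
        species: Species,
        positions: np.ndarray,
        charge: float,
        radius: float,
        chain_id: Optional[int] = None,
        fixed: bool = False,
    ) -> np.ndarray:
        """Append beads of one species; returns their indices.

        ``chain_id=None`` assigns a fresh chain per call.
        """
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        if chain_id is None:
            chain_id = self.n_chains
        start = self.n_beads
        self.species = np.concatenate([self.species, np.full(n, int(species), dtype=np.int64)])
        self.charge = np.concatenate([self.charge, np.full(n, float(charge))])
        self.radius = np.concatenate([self.radius, np.full(n, float(radius))])
        self.position = np.vstack([self.position, positions])
        self.chain_id = np.concatenate([self.chain_id, np.full(n, chain_id, dtype=np.int64)])
        self.fixed = np.concatenate([self.fixed, np.full(n, fixed, dtype=bool)])
        return np.arange(start, start + n)

    def add_bonds(self, pairs: Iterable, r0: float, k: float) -> None:
        pairs = np.atleast_2d(np.asarray(list(pairs), dtype=np.int64))
        if pairs.size == 0:
            return
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("a bond cannot join a bead to itself")
        if r0 <= 0:
            raise ValueError("bond rest length must be positive")
        self.bond_i = np.concatenate([self.bond_i, pairs[:, 0]])
        self.bond_j = np.concatenate([self.bond_j, pairs[:, 1]])
        self.bond_r0 = np.concatenate([self.bond_r0, np.full(len(pairs), float(r0))])
        self.bond_k = np.concatenate([self.bond_k, np.full(len(pairs), float(k))])

    def add_angles(self, triples: Iterable, theta0: float, kappa: float) -> None:
        triples = np.atleast_2d(np.asarray(list(triples), dtype=np.int64))
        if triples.size == 0:
            return
        self.angle_i = np.concatenate([self.angle_i, triples[:, 0]])
        self.angle_j = np.concatenate([self.angle_j, triples[:, 1]])
        self.angle_k = np.concatenate([self.angle_k, triples[:, 2]])
        self.angle_theta0 = np.concatenate([self.angle_theta0, np.full(len(triples), float(theta0))])
        self.angle_kappa = np.concatenate([self.angle_kappa, np.full(len(triples), float(kappa))])

    def total_charge(self) -> float:
        return float(self.charge.sum())

    def mobile_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.fixed)

    def validate(self) -> None:
        """Raise if structural invariants are violated."""
        n = self.n_beads
        for name in ("charge", "radius", "chain_id", "fixed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"bead column {name} has wrong length")
        if self.position.shape != (n, 3):
            raise ValueError("position table has wrong shape")
        if np.any(self.radius <= 0):
            raise ValueError("bead radii must be positive")
        if self.n_bonds:
            if np.any(self.bond_i == self.bond_j):
                raise ValueError("bond joins a bead to itself")
            if np.any(self.bond_r0 <= 0):
                raise ValueError("bond rest lengths must be positive")
            if self.bond_i.max() >= n or self.bond_j.max() >= n:
                raise ValueError("bond references missing bead")
            if np.any(self.fixed[self.bond_i] & self.fixed[self.bond_j]):
                raise ValueError("bond connects two fixed beads")
        if np.any(self.species == int(Species.CORE)):
            if not np.all(self.fixed[self.species == int(Species.CORE)]):
                raise ValueError("all CORE beads must be fixed")

    def copy(self) -> "CGTopology":
        return CGTopology(**{
            f.name: getattr(self, f.name).copy()
            for f in self.__dataclass_fields__.values()  # type: ignore[attr-defined]
        })

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bead_id": np.arange(self.n_beads),
            "species": [Species(s).name for s in self.species],
            "charge": self.charge,
            "radius": self.radius,
            "x": self.position[:, 0],
            "y": self.position[:, 1],
            "z": self.position[:, 2],
            "chain_id": self.chain_id,
            "fixed": self.fixed,
        })
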