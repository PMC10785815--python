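"""Pairwise and bonded interactions.

Energy model (all energies in k_BT, lengths in nm):

* harmonic bonds U = k/2 (r - r0)^2 and harmonic angles U = kappa/2 (theta - theta0)^2;
* WCA excluded volume between all pairs, with the repulsion vanishing exactly
  at the sum of bead radii (sigma = contact / 2^(1/6));
* screened Coulomb (Debye-Hueckel) U = l_B q_i q_j exp(-r/lambda_D) / r between
  charged pairs, smoothly switched off at the pair cutoff;
* a short-range attractive well (the attractive branch of a WCA-split
  Lennard-Jones) between precursors and DNA beads, the effective stand-in for
  silane condensation chemistry.  Its depth ``attraction_epsilon`` is the one
  calibrated scalar of the model and is identical for CORE, SS and DS beads:
  any brush selectivity must emerge from charge and geometry.

The functions in this module are the readable scalar/numpy reference; the
numba kernels in :mod:`silicabrush.kernels` implement the same model for the
integrator and are cross-checked against this path in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .constants import (
    BJERRUM_WATER_298K,
    T_REF,
    debye_length_nm,
    thermal_energy_kcal_per_mol,
)
from .topology import BoxSpec, CGTopology, Species

__all__ = [
    "ForceFieldParams",
    "debye_length",
    "pair_energy",
    "pair_energy_force",
    "bruteforce_energy_forces",
    "KBT_KCAL_PER_MOL",
]

#: Thermal energy at 298 K in kcal/mol (~0.6), exposed for unit conversions.
KBT_KCAL_PER_MOL = thermal_energy_kcal_per_mol(T_REF)

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)

#: Calibrated depth (k_BT) of the precursor-DNA condensation well.  This is
#: the single tuned scalar of the model: it was calibrated once so that the
#: double-stranded-brush system reproduces the ~54% condensation enhancement,
#: then frozen for every other analysis (single-strand, retention, scans).
DEFAULT_ATTRACTION_EPSILON = 1.4

#: Default salt condition: 5 mM Mg2+ (the working silicification buffer),
#: treated implicitly through the Debye length (2.48 nm).
DEFAULT_MONO_MM = 0.0
DEFAULT_DI_MM = 5.0


def debye_length(mono_mM: float, di_mM: float, temperature: float = T_REF) -> float:
    """Debye screening length (nm); see :func:`silicabrush.constants.debye_length_nm`."""
    return debye_length_nm(mono_mM, di_mM, temperature)


@dataclass(frozen=True)
class ForceFieldParams:
    bjerrum_length: float = BJERRUM_WATER_298K  # nm
    debye_length: float = field(
        default_factory=lambda: debye_length_nm(DEFAULT_MONO_MM, DEFAULT_DI_MM)
    )  # nm
    wca_epsilon: float = 1.0  # k_BT
    attraction_epsilon: float = DEFAULT_ATTRACTION_EPSILON  # k_BT
    attraction_range: float = 1.0  # nm beyond contact
    pair_cutoff: float = 5.0  # nm
    switch_fraction: float = 0.9  # switching starts at this fraction of each cutoff
    precursor_precursor_attraction: bool = False

    def __post_init__(self) -> None:
        for name in ("bjerrum_length", "debye_length", "attraction_range", "pair_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.switch_fraction < 1.0):
            raise ValueError("switch_fraction must lie in (0, 1)")
        if self.wca_epsilon < 0 or self.attraction_epsilon < 0:
            raise ValueError("epsilons must be non-negative")

    def with_salt(self, mono_mM: float, di_mM: float, temperature: float = T_REF) -> "ForceFieldParams":
        return replace(self, debye_length=debye_length_nm(mono_mM, di_mM, temperature))


def _attracting(sp_i: int, sp_j: int, params: ForceFieldParams) -> bool:
    dna = (int(Species.CORE), int(Species.SS_BEAD), int(Species.DS_BEAD))
    pre = int(Species.PRECURSOR)
    if (sp_i == pre and sp_j in dna) or (sp_j == pre and sp_i in dna):
        return True
    if params.precursor_precursor_attraction and sp_i == pre and sp_j == pre:
        return True
    return False


def _switch(r: float, r_on: float, r_off: float) -> Tuple[float, float]:
    """XPLOR switching function S(r) and dS/dr (C1, 1 below r_on, 0 above r_off)."""
    if r <= r_on:
        return 1.0, 0.0
    if r >= r_off:
        return 0.0, 0.0
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    denom = (off2 - on2) ** 3
    s = (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / denom
    ds = 12.0 * r * (off2 - r2) * (on2 - r2) / denom
    return s, ds


def _wca(r: float, contact: float, eps: float) -> Tuple[float, float]:
    """WCA energy and dU/dr; repulsion vanishes at r = contact."""
    if r >= contact or eps == 0.0:
        return 0.0, 0.0
    sigma = contact / _SIXTH_ROOT_2
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6) + eps
    du = -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return u, du


def _debye_hueckel(r: float, qq: float, params: ForceFieldParams) -> Tuple[float, float]:
    if qq == 0.0 or r >= params.pair_cutoff:
        return 0.0, 0.0
    lb, ld = params.bjerrum_length, params.debye_length
    u0 = lb * qq * math.exp(-r / ld) / r
    du0 = -u0 * (1.0 / r + 1.0 / ld)
    s, ds = _switch(r, params.switch_fraction * params.pair_cutoff, params.pair_cutoff)
    return u0 * s, du0 * s + u0 * ds


def _attraction_well(r: float, contact: float, params: ForceFieldParams) -> Tuple[float, float]:
    """WCA-split attractive LJ branch: -eps inside contact, LJ tail outside,
    switched to zero at contact + attraction_range."""
    eps = params.attraction_epsilon
    r_off = contact + params.attraction_range
    if eps == 0.0 or r >= r_off:
        return 0.0, 0.0
    if r <= contact:
        return -eps, 0.0
    sigma = contact / _SIXTH_ROOT_2
    sr6 = (sigma / r) ** 6
    u0 = 4.0 * eps * (sr6 * sr6 - sr6)
    du0 = -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    r_on = contact + params.switch_fraction * params.attraction_range
    s, ds = _switch(r, r_on, r_off)
    return u0 * s, du0 * s + u0 * ds


def pair_energy_force(
    species_i: int,
    species_j: int,
    q_i: float,
    q_j: float,
    r: float,
    params: ForceFieldParams,
    radius_i: float = 0.5,
    radius_j: float = 0.5,
) -> Tuple[float, float]:
    """Nonbonded pair energy (k_BT) and radial derivative dU/dr (k_BT/nm)."""
    if r <= 0:
        raise ValueError("pair separation must be positive")
    if r >= params.pair_cutoff:
        return 0.0, 0.0
    contact = radius_i + radius_j
    u, du = _wca(r, contact, params.wca_epsilon)
    ue, due = _debye_hueckel(r, q_i * q_j, params)
    u, du = u + ue, du + due
    if _attracting(int(species_i), int(species_j), params):
        ua, dua = _attraction_well(r, contact, params)
        u, du = u + ua, du + dua
    return u, du


def pair_energy(
    species_i: int,
    species_j: int,
    q_i: float,
    q_j: float,
    r: float,
    params: ForceFieldParams,
    radius_i: float = 0.5,
    radius_j: float = 0.5,
) -> float:
    """Nonbonded pair energy (k_BT); zero beyond the pair cutoff."""
    return pair_energy_force(species_i, species_j, q_i, q_j, r, params, radius_i, radius_j)[0]


def minimum_image(d: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Apply the minimum-image convention on periodic axes of displacement(s) d."""
    d = np.array(d, dtype=float, copy=True)
    for ax in range(3):
        if box.periodic[ax]:
            L = box.lengths[ax]
            d[..., ax] -= L * np.round(d[..., ax] / L)
    return d


def bruteforce_energy_forces(
    topo: CGTopology,
    box: BoxSpec,
    params: ForceFieldParams,
    positions: Optional[np.ndarray] = None,
) -> Tuple[float, np.ndarray]:
    """O(N^2) reference total energy and per-bead forces.

    Independent of the neighbour-list kernels; used as the oracle in tests.
    Directly bonded pairs are excluded from the nonbonded sum.
    """
    pos = topo.position if positions is None else np.asarray(positions, dtype=float)
    n = len(pos)
    forces = np.zeros((n, 3))
    energy = 0.0
    bonded = set(zip(topo.bond_i.tolist(), topo.bond_j.tolist()))
    bonded |= {(j, i) for i, j in bonded}
    cutoff = params.pair_cutoff
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            d = minimum_image(pos[i] - pos[j], box)
            r = float(np.linalg.norm(d))
            if r >= cutoff:
                continue
            u, du = pair_energy_force(
                topo.species[i], topo.species[j], topo.charge[i], topo.charge[j],
                r, params, topo.radius[i], topo.radius[j],
            )
            energy += u
            f = -du / r * d
            forces[i] += f
            forces[j] -= f
    # bonds
    for b in range(topo.n_bonds):
        i, j = topo.bond_i[b], topo.bond_j[b]
        d = minimum_image(pos[i] - pos[j], box)
        r = float(np.linalg.norm(d))
        energy += 0.5 * topo.bond_k[b] * (r - topo.bond_r0[b]) ** 2
        du = topo.bond_k[b] * (r - topo.bond_r0[b])
        f = -du / r * d
        forces[i] += f
        forces[j] -= f
    # angles
    for a in range(topo.n_angles):
        i, j, k = topo.angle_i[a], topo.angle_j[a], topo.angle_k[a]
        u1 = minimum_image(pos[i] - pos[j], box)
        u2 = minimum_image(pos[k] - pos[j], box)
        n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
        c = float(np.dot(u1, u2) / (n1 * n2))
        c = min(1.0, max(-1.0, c))
        theta = math.acos(c)
        dtheta = theta - topo.angle_theta0[a]
        energy += 0.5 * topo.angle_kappa[a] * dtheta ** 2
        s = math.sqrt(max(1.0 - c * c, 1e-12))
        coef = topo.angle_kappa[a] * dtheta / s  # = -dU/dcos(theta)
        fi = coef * (u2 / (n1 * n2) - c * u1 / (n1 * n1))
        fk = coef * (u1 / (n1 * n2) - c * u2 / (n2 * n2))
        forces[i] += fi
        forces[k] += fk
        forces[j] -= fi + fk
    return energy, forces
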