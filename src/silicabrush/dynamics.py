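"""Overdamped Brownian (position-Langevin) dynamics.

Mobile beads follow x <- x + (dt/gamma) F + sqrt(2 k_BT dt / gamma) xi with
independent standard-normal xi per coordinate; CORE beads are a fixed
template and are never moved.  Energies are expressed in k_BT, so the
thermal energy is unity and temperature enters the model only through the
Debye length and unit conversions.  Friction is Stokes-like,
gamma = gamma_per_radius * bead radius, so larger beads diffuse more slowly
(D = 1/gamma in reduced units).

A single seeded NumPy generator drives all noise; identical
(system, parameters, seed) therefore reproduce bit-identical trajectories
on a single thread.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import kernels
from .forcefield import ForceFieldParams
from .neighbors import exclusion_codes
from .topology import BoxSpec, CGTopology, Species

__all__ = [
    "IntegratorParams",
    "SimulationState",
    "Trajectory",
    "InstabilityError",
    "total_forces",
    "total_energy",
    "step",
    "run",
]


class InstabilityError(RuntimeError):
    """A bead moved more than the stability limit in one step (dt too large)."""


@dataclass(frozen=True)
class IntegratorParams:
    dt: float = 0.001            # reduced time tau
    n_steps: int = 1000
    frame_stride: int = 100
    temperature: float = 298.0   # K; informational (energies are in k_BT)
    gamma_per_radius: float = 2.0  # gamma_i = gamma_per_radius * radius_i
    skin: float = 1.0            # nm, neighbour-list skin
    seed: int = 0
    max_step_displacement: float = 1.0  # nm, instability threshold
    max_force_displacement: float = 0.2  # nm, clamp on the deterministic part
    relax_steps: int = 500       # zero-noise quench steps before production
    relax_dt_factor: float = 0.1  # quench dt = relax_dt_factor * dt

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    def gamma(self, radius: np.ndarray) -> np.ndarray:
        return self.gamma_per_radius * np.asarray(radius, dtype=float)


@dataclass
class SimulationState:
    positions: np.ndarray
    time: float
    box: BoxSpec

    def copy(self) -> "SimulationState":
        return SimulationState(self.positions.copy(), self.time, self.box)


@dataclass
class Trajectory:
    """Ordered frames plus provenance metadata."""

    frames: np.ndarray          # (n_frames, n_beads, 3)
    times: np.ndarray           # (n_frames,) in tau
    box: BoxSpec
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def analysis_window(self, fraction: float = 0.5) -> np.ndarray:
        """Frame indices of the trailing analysis window (default: last half)."""
        start = int(np.ceil(self.n_frames * (1.0 - fraction)))
        return np.arange(min(start, self.n_frames - 1), self.n_frames)


def _kernel_args(topo: CGTopology, box: BoxSpec, ff: ForceFieldParams):
    att = np.zeros((len(Species), len(Species)))
    dna = [int(Species.CORE), int(Species.SS_BEAD), int(Species.DS_BEAD)]
    pre = int(Species.PRECURSOR)
    for s in dna:
        att[pre, s] = att[s, pre] = ff.attraction_epsilon
    if ff.precursor_precursor_attraction:
        att[pre, pre] = ff.attraction_epsilon
    return dict(
        box_l=box.lengths,
        periodic=box.periodic,
        charge=topo.charge,
        radius=topo.radius,
        species=topo.species,
        att_mat=att,
        wca_eps=ff.wca_epsilon,
        lb=ff.bjerrum_length,
        ld=ff.debye_length,
        cutoff=ff.pair_cutoff,
        switch_frac=ff.switch_fraction,
        att_range=ff.attraction_range,
        bond_i=topo.bond_i, bond_j=topo.bond_j,
        bond_r0=topo.bond_r0, bond_k=topo.bond_k,
        ang_i=topo.angle_i, ang_j=topo.angle_j, ang_k=topo.angle_k,
        ang_t0=topo.angle_theta0, ang_kap=topo.angle_kappa,
    )


def total_forces(
    topo: CGTopology,
    box: BoxSpec,
    ff: ForceFieldParams,
    positions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exact forces on every bead (fixed beads included) via the kernel path."""
    pos = np.ascontiguousarray(topo.position if positions is None else positions, float)
    from .neighbors import build_neighbor_list

    ka = _kernel_args(topo, box, ff)
    nl = build_neighbor_list(topo, box, ff.pair_cutoff, skin=0.0,
                             positions=pos, include_fixed_pairs=True,
                             att_mat=ka["att_mat"])
    forces = np.zeros_like(pos)
    kernels.compute_forces(pos, ka["box_l"], ka["periodic"],
                           ka["wca_eps"], ka["lb"], ka["ld"], ka["cutoff"],
                           ka["switch_frac"], ka["att_range"],
                           nl.pair_i, nl.pair_j, nl.pair_qq, nl.pair_contact,
                           nl.pair_att, nl.n_pairs,
                           ka["bond_i"], ka["bond_j"], ka["bond_r0"], ka["bond_k"],
                           ka["ang_i"], ka["ang_j"], ka["ang_k"],
                           ka["ang_t0"], ka["ang_kap"], forces)
    return forces


def total_energy(
    topo: CGTopology,
    box: BoxSpec,
    ff: ForceFieldParams,
    positions: Optional[np.ndarray] = None,
) -> float:
    """Total potential energy (k_BT) via the neighbour-list kernel path."""
    pos = np.ascontiguousarray(topo.position if positions is None else positions, float)
    from .neighbors import build_neighbor_list

    ka = _kernel_args(topo, box, ff)
    nl = build_neighbor_list(topo, box, ff.pair_cutoff, skin=0.0,
                             positions=pos, include_fixed_pairs=True,
                             att_mat=ka["att_mat"])
    forces = np.zeros_like(pos)
    return float(kernels.compute_forces(
        pos, ka["box_l"], ka["periodic"], ka["wca_eps"], ka["lb"], ka["ld"],
        ka["cutoff"], ka["switch_frac"], ka["att_range"],
        nl.pair_i, nl.pair_j, nl.pair_qq, nl.pair_contact, nl.pair_att,
        nl.n_pairs,
        ka["bond_i"], ka["bond_j"], ka["bond_r0"], ka["bond_k"],
        ka["ang_i"], ka["ang_j"], ka["ang_k"], ka["ang_t0"], ka["ang_kap"],
        forces))


class _Engine:
    """Mutable integration state shared by step() and run()."""

    def __init__(self, topo: CGTopology, box: BoxSpec, ff: ForceFieldParams,
                 ip: IntegratorParams, positions: Optional[np.ndarray] = None):
        topo.validate()
        self.topo, self.box, self.ff, self.ip = topo, box, ff, ip
        self.pos = np.ascontiguousarray(
            topo.position if positions is None else positions, dtype=float).copy()
        self.mobile = ~topo.fixed
        self.mobile_idx = np.flatnonzero(self.mobile)
        gam = ip.gamma(topo.radius[self.mobile_idx])
        self.inv_gamma = 1.0 / gam
        self.excl = exclusion_codes(topo)
        self.ka = _kernel_args(topo, box, ff)
        n = topo.n_beads
        cap = max(1024, 16 * max(1, len(self.mobile_idx)))
        self._alloc_pairs(cap)
        self.npairs = np.array([-1], dtype=np.int64)
        self.ref_pos = np.zeros_like(self.pos)
        self.forces = np.zeros_like(self.pos)
        self.rng = np.random.default_rng(ip.seed)
        self.time = 0.0

    def _alloc_pairs(self, cap: int) -> None:
        self.pair_i = np.empty(cap, dtype=np.int64)
        self.pair_j = np.empty(cap, dtype=np.int64)
        self.pair_qq = np.empty(cap, dtype=float)
        self.pair_contact = np.empty(cap, dtype=float)
        self.pair_att = np.empty(cap, dtype=float)

    def quench(self, n_steps: Optional[int] = None) -> None:
        """Deterministic overdamped descent to relax build-time overlaps.

        Runs with zero noise at a reduced time step; does not advance the
        simulation clock.
        """
        n = self.ip.relax_steps if n_steps is None else n_steps
        if n <= 0:
            return
        noise_zero = np.zeros((n, len(self.mobile_idx), 3))
        self._advance_noise(noise_zero, dt=self.ip.dt * self.ip.relax_dt_factor)
        self.npairs[0] = -1

    def _advance_noise(self, noise: np.ndarray, dt: Optional[float] = None) -> None:
        dt = self.ip.dt if dt is None else dt
        taken = 0
        m = noise.shape[0]
        while taken < m:
            ka = self.ka
            steps, status = kernels.advance(
                self.pos, ka["box_l"], ka["periodic"], ka["charge"],
                ka["radius"], ka["species"], ka["att_mat"], ka["wca_eps"],
                ka["lb"], ka["ld"], ka["cutoff"], ka["switch_frac"],
                ka["att_range"],
                ka["bond_i"], ka["bond_j"], ka["bond_r0"], ka["bond_k"],
                ka["ang_i"], ka["ang_j"], ka["ang_k"], ka["ang_t0"],
                ka["ang_kap"],
                self.mobile, self.mobile_idx, self.inv_gamma,
                noise[taken:], dt, self.ip.skin,
                self.excl, self.pair_i, self.pair_j, self.pair_qq,
                self.pair_contact, self.pair_att, self.npairs,
                self.ref_pos, self.forces, self.ip.max_step_displacement,
                self.ip.max_force_displacement)
            taken += int(steps)
            if status == kernels.STATUS_UNSTABLE:
                raise InstabilityError(
                    f"bead displacement exceeded {self.ip.max_step_displacement} nm "
                    f"at t={self.time + taken * dt:.4f} tau; reduce dt")
            if status == kernels.STATUS_OVERFLOW:
                self._alloc_pairs(2 * len(self.pair_i))
                self.npairs[0] = -1

    def advance(self, n_steps: int, chunk: int = 2000) -> None:
        done = 0
        while done < n_steps:
            m = min(chunk, n_steps - done)
            noise = self.rng.standard_normal((m, len(self.mobile_idx), 3))
            self._advance_noise(noise)
            done += m
        self.time += n_steps * self.ip.dt


def step(
    state: SimulationState,
    topo: CGTopology,
    ff: ForceFieldParams,
    ip: IntegratorParams,
    n_steps: int = 1,
) -> SimulationState:
    """Advance a state by n_steps and return the new state (n_steps=0 is a no-op)."""
    if n_steps == 0:
        return state.copy()
    eng = _Engine(topo, state.box, ff, ip, positions=state.positions)
    eng.advance(n_steps)
    return SimulationState(eng.pos.copy(), state.time + n_steps * ip.dt, state.box)


def _params_hash(ff: ForceFieldParams, ip: IntegratorParams) -> str:
    payload = json.dumps({"ff": asdict(ff), "ip": asdict(ip)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(
    topo: CGTopology,
    box: BoxSpec,
    ff: ForceFieldParams,
    ip: IntegratorParams,
    initial_positions: Optional[np.ndarray] = None,
    equilibration_fraction: float = 0.5,
) -> Trajectory:
    """Integrate n_steps and record frames every frame_stride steps.

    The first frame is the initial configuration; the final configuration is
    always recorded.  Metadata carries the seed, a parameter hash and the
    declared equilibration window so analyses can report it.
    """
    eng = _Engine(topo, box, ff, ip, positions=initial_positions)
    eng.quench()
    frames = [eng.pos.copy()]
    times = [0.0]
    remaining = ip.n_steps
    while remaining > 0:
        m = min(ip.frame_stride, remaining)
        eng.advance(m)
        remaining -= m
        frames.append(eng.pos.copy())
        times.append(eng.time)
    meta = {
        "seed": ip.seed,
        "dt": ip.dt,
        "n_steps": ip.n_steps,
        "frame_stride": ip.frame_stride,
        "params_hash": _params_hash(ff, ip),
        "equilibration_fraction": equilibration_fraction,
    }
    return Trajectory(np.asarray(frames), np.asarray(times), box, meta)
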