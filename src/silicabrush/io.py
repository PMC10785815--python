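"""File I/O: topology (PDB + JSON sidecar), trajectories (XYZ / HDF5),
tidy CSV results and provenance records."""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .topology import Boundary, BoxSpec, CGTopology, Species
from .dynamics import Trajectory

__all__ = [
    "SPECIES_ELEMENTS",
    "write_xyz",
    "read_xyz_frames",
    "write_pdb",
    "write_topology_json",
    "read_topology_json",
    "write_trajectory_h5",
    "read_trajectory_h5",
    "write_provenance",
]

#: Element symbols used for the species column of XYZ/PDB output (a visual
#: convention for trajectory viewers, recorded in every metadata sidecar).
SPECIES_ELEMENTS = {
    Species.CORE: "C",
    Species.SS_BEAD: "N",
    Species.DS_BEAD: "O",
    Species.PRECURSOR: "P",
    Species.ION_MONO: "Na",
    Species.ION_DI: "Mg",
}

_RESNAMES = {
    Species.CORE: "COR",
    Species.SS_BEAD: "SSB",
    Species.DS_BEAD: "DSB",
    Species.PRECURSOR: "PRE",
    Species.ION_MONO: "IOM",
    Species.ION_DI: "IOD",
}


def write_xyz(path: str | Path, topo: CGTopology, frames: np.ndarray,
              times: Optional[Sequence[float]] = None) -> None:
    """Write frames in extended-XYZ style (element = species symbol)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, ...]
    symbols = [SPECIES_ELEMENTS[Species(s)] for s in topo.species]
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{topo.n_beads}\n")
            t = times[f] if times is not None else f
            fh.write(f"frame={f} time={t}\n")
            for sym, (x, y, z) in zip(symbols, frame):
                fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(path: str | Path):
    """Read an XYZ file back as (symbols, frames array)."""
    frames: List[np.ndarray] = []
    symbols: List[str] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            rows = []
            syms = []
            for _ in range(n):
                parts = fh.readline().split()
                syms.append(parts[0])
                rows.append([float(v) for v in parts[1:4]])
            frames.append(np.asarray(rows))
            if not symbols:
                symbols = syms
    return symbols, np.asarray(frames)


def write_pdb(path: str | Path, topo: CGTopology, box: Optional[BoxSpec] = None) -> None:
    """Write beads as pseudo-atoms, one residue per chain, species in resname."""
    import MDAnalysis as mda

    n = topo.n_beads
    chains, chain_index = np.unique(topo.chain_id, return_inverse=True)
    u = mda.Universe.empty(n, n_residues=len(chains), n_segments=1,
                           atom_resindex=chain_index,
                           residue_segindex=np.zeros(len(chains), dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [SPECIES_ELEMENTS[Species(s)] for s in topo.species])
    resnames = [
        _RESNAMES[Species(topo.species[np.flatnonzero(topo.chain_id == c)[0]])]
        for c in chains
    ]
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", (np.arange(len(chains)) % 9999) + 1)
    u.atoms.positions = topo.position.astype(np.float32) * 10.0  # nm -> Angstrom
    if box is not None:
        u.dimensions = [*(box.lengths * 10.0), 90.0, 90.0, 90.0]
    u.atoms.write(str(path))


def write_topology_json(path: str | Path, topo: CGTopology,
                        box: Optional[BoxSpec] = None,
                        extra: Optional[Dict] = None) -> None:
    """Full lossless topology record (positions included)."""
    payload = {
        "version": __version__,
        "species": topo.species.tolist(),
        "charge": topo.charge.tolist(),
        "radius": topo.radius.tolist(),
        "position": topo.position.tolist(),
        "chain_id": topo.chain_id.tolist(),
        "fixed": topo.fixed.tolist(),
        "bonds": {
            "i": topo.bond_i.tolist(), "j": topo.bond_j.tolist(),
            "r0": topo.bond_r0.tolist(), "k": topo.bond_k.tolist(),
        },
        "angles": {
            "i": topo.angle_i.tolist(), "j": topo.angle_j.tolist(),
            "k": topo.angle_k.tolist(), "theta0": topo.angle_theta0.tolist(),
            "kappa": topo.angle_kappa.tolist(),
        },
        "species_elements": {Species(s).name: e for s, e in SPECIES_ELEMENTS.items()},
    }
    if box is not None:
        payload["box"] = {"lengths": box.lengths.tolist(),
                          "boundary": box.boundary.tolist()}
    if extra:
        payload["extra"] = extra
    Path(path).write_text(json.dumps(payload))


def read_topology_json(path: str | Path):
    """Inverse of :func:`write_topology_json`; returns (topology, box or None)."""
    data = json.loads(Path(path).read_text())
    topo = CGTopology(
        species=np.asarray(data["species"], dtype=np.int64),
        charge=np.asarray(data["charge"], dtype=float),
        radius=np.asarray(data["radius"], dtype=float),
        position=np.asarray(data["position"], dtype=float),
        chain_id=np.asarray(data["chain_id"], dtype=np.int64),
        fixed=np.asarray(data["fixed"], dtype=bool),
        bond_i=np.asarray(data["bonds"]["i"], dtype=np.int64),
        bond_j=np.asarray(data["bonds"]["j"], dtype=np.int64),
        bond_r0=np.asarray(data["bonds"]["r0"], dtype=float),
        bond_k=np.asarray(data["bonds"]["k"], dtype=float),
        angle_i=np.asarray(data["angles"]["i"], dtype=np.int64),
        angle_j=np.asarray(data["angles"]["j"], dtype=np.int64),
        angle_k=np.asarray(data["angles"]["k"], dtype=np.int64),
        angle_theta0=np.asarray(data["angles"]["theta0"], dtype=float),
        angle_kappa=np.asarray(data["angles"]["kappa"], dtype=float),
    )
    box = None
    if "box" in data:
        box = BoxSpec(data["box"]["lengths"],
                      [Boundary(b) for b in data["box"]["boundary"]])
    return topo, box


def write_trajectory_h5(path: str | Path, traj: Trajectory) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=traj.frames, compression="gzip")
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("box_lengths", data=traj.box.lengths)
        h5.create_dataset("box_boundary", data=traj.box.boundary)
        h5.attrs["metadata"] = json.dumps(traj.metadata)


def read_trajectory_h5(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        frames = h5["frames"][...]
        times = h5["times"][...]
        box = BoxSpec(h5["box_lengths"][...],
                      [Boundary(int(b)) for b in h5["box_boundary"][...]])
        meta = json.loads(h5.attrs["metadata"])
    return Trajectory(frames, times, box, meta)


def write_provenance(path: str | Path, config_dict: Dict, seed: Optional[int] = None,
                     extra: Optional[Dict] = None) -> Dict:
    """Provenance JSON: package version, config + hash, seed."""
    record = {
        "package": "silicabrush",
        "version": __version__,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest()[:16],
    }
    if seed is not None:
        record["seed"] = seed
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=1))
    return record
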