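"""Neighbour-list wrapper over the cell-list kernel."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kernels import build_pairs
from .topology import BoxSpec, CGTopology

__all__ = ["NeighborList", "build_neighbor_list", "bruteforce_pairs", "exclusion_codes"]


def exclusion_codes(topo: CGTopology) -> np.ndarray:
    """Sorted codes i*N+j (i<j) of nonbonded-excluded (directly bonded) pairs."""
    n = topo.n_beads
    i = np.minimum(topo.bond_i, topo.bond_j).astype(np.int64)
    j = np.maximum(topo.bond_i, topo.bond_j).astype(np.int64)
    return np.sort(i * n + j)


@dataclass
class NeighborList:
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_qq: np.ndarray
    pair_contact: np.ndarray
    pair_att: np.ndarray
    n_pairs: int
    cutoff: float
    skin: float
    ref_pos: np.ndarray

    def pairs(self) -> np.ndarray:
        return np.column_stack([self.pair_i[: self.n_pairs], self.pair_j[: self.n_pairs]])

    def pair_set(self) -> set:
        return {tuple(sorted(p)) for p in self.pairs().tolist()}

    def is_stale(self, pos: np.ndarray, box: BoxSpec) -> bool:
        """True if any bead moved more than skin/2 since the build."""
        d = pos - self.ref_pos
        for ax in range(3):
            if box.periodic[ax]:
                L = box.lengths[ax]
                d[:, ax] -= L * np.round(d[:, ax] / L)
        return bool(np.max(np.einsum("ij,ij->i", d, d)) > (0.5 * self.skin) ** 2)


def build_neighbor_list(
    topo: CGTopology,
    box: BoxSpec,
    cutoff: float,
    skin: float = 1.0,
    positions: Optional[np.ndarray] = None,
    include_fixed_pairs: bool = True,
    att_mat: Optional[np.ndarray] = None,
) -> NeighborList:
    """All pairs within cutoff+skin (directly bonded pairs excluded).

    Raises if cutoff+skin exceeds half the box on a periodic axis, where the
    minimum-image convention would miss images.
    """
    if cutoff < 0 or skin < 0:
        raise ValueError("cutoff and skin must be non-negative")
    rlist = cutoff + skin
    for ax in range(3):
        if box.periodic[ax] and rlist > box.lengths[ax] / 2.0:
            raise ValueError(
                f"cutoff+skin={rlist} exceeds half the box on periodic axis {ax}"
            )
    pos = np.ascontiguousarray(topo.position if positions is None else positions, dtype=float)
    n = len(pos)
    mobile = ~topo.fixed
    excl = exclusion_codes(topo)
    if att_mat is None:
        att_mat = np.zeros((8, 8))
    cap = max(1024, 8 * n)
    while True:
        pair_i = np.empty(cap, dtype=np.int64)
        pair_j = np.empty(cap, dtype=np.int64)
        pair_qq = np.empty(cap, dtype=float)
        pair_contact = np.empty(cap, dtype=float)
        pair_att = np.empty(cap, dtype=float)
        cnt = build_pairs(pos, box.lengths, box.periodic, rlist, mobile,
                          include_fixed_pairs, excl, topo.charge, topo.radius,
                          topo.species, att_mat,
                          pair_i, pair_j, pair_qq, pair_contact, pair_att)
        if cnt >= 0:
            return NeighborList(pair_i, pair_j, pair_qq, pair_contact, pair_att,
                                int(cnt), cutoff, skin, pos.copy())
        cap *= 2


def bruteforce_pairs(topo: CGTopology, box: BoxSpec, rlist: float,
                     positions: Optional[np.ndarray] = None) -> set:
    """O(N^2) oracle pair set (numpy, independent of the cell-list code)."""
    pos = topo.position if positions is None else positions
    n = len(pos)
    excl = {tuple(sorted(p)) for p in zip(topo.bond_i.tolist(), topo.bond_j.tolist())}
    out = set()
    for i in range(n - 1):
        d = pos[i + 1:] - pos[i]
        for ax in range(3):
            if box.periodic[ax]:
                L = box.lengths[ax]
                d[:, ax] -= L * np.round(d[:, ax] / L)
        r2 = np.einsum("ij,ij->i", d, d)
        for off in np.flatnonzero(r2 < rlist * rlist):
            pair = (i, i + 1 + int(off))
            if pair not in excl:
                out.add(pair)
    return out
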