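"""Construction of the simulated system.

The bundle core is a rigid template: six straight strings of fixed beads
whose helix centres sit on a 2 nm ring, giving the 6 nm envelope of a
six-helix bundle.  Brushes are bead-spring chains grafted at layout-derived
sites: single-stranded chains are flexible and weakly charged, double-
stranded chains are stiff (worm-like, ~50 nm persistence length) and carry
twice the linear charge density.  Cationic silica precursors and optional
explicit ions are placed uniformly at random with a minimum-separation
constraint.  All randomness flows through one seeded generator, so the
builder is a pure function of (layout, parameters, seed).

Default bead mapping (charges are Manning-renormalized effective values):

======== ===== ========= ======== ============ ==============
species   maps  bond nm   charge   radius nm    bending kappa
======== ===== ========= ======== ============ ==============
CORE     2 bp      --      -1.0 e     1.0            --
SS_BEAD  3 nt     1.5     -0.75 e     0.5           0 (FJC)
DS_BEAD  3 bp     1.0     -1.5 e      0.5        50 k_BT/rad^2
======== ===== ========= ======== ============ ==============
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .constants import AVOGADRO, DOMAIN_LENGTH_NM
from .layout import BrushKind, BrushLayoutSpec, GraftSite, enumerate_graft_sites
from .topology import Boundary, BoxSpec, CGTopology, Species

__all__ = [
    "GeometryParams",
    "BrushParams",
    "SS_BRUSH",
    "DS_BRUSH",
    "GeometryError",
    "PackingError",
    "build_core",
    "attach_brushes",
    "place_precursors",
    "add_salt",
    "default_box",
    "build_system",
    "BuiltSystem",
]

N_HELICES = 6


class GeometryError(ValueError):
    pass


class PackingError(RuntimeError):
    """Random placement failed to satisfy the minimum-separation constraint."""


@dataclass(frozen=True)
class GeometryParams:
    """Rigid-core geometry of the six-helix bundle."""

    bundle_length: float  # nm
    helix_ring_radius: float = 2.0  # nm, ring of helix centres
    helix_radius: float = 1.0  # nm, radius of one duplex
    core_bead_spacing: float = 0.68  # nm, 2 bp per bead
    rise_per_bp: float = 0.34  # nm/bp
    core_charge: float = -1.0  # e per bead (renormalized 2 bp)

    def __post_init__(self) -> None:
        if self.bundle_length < self.core_bead_spacing:
            raise GeometryError("bundle_length must be >= core_bead_spacing")
        for name in ("helix_ring_radius", "helix_radius", "core_bead_spacing", "rise_per_bp"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")

    @property
    def envelope_diameter(self) -> float:
        """Maximal cross-section extent of the bundle (6.0 nm at defaults)."""
        return 2.0 * (self.helix_ring_radius + self.helix_radius)

    @property
    def core_surface_radius(self) -> float:
        return self.helix_ring_radius + self.helix_radius

    @property
    def beads_per_helix(self) -> int:
        """Beads per helix string, floor(L/spacing)+1; when the final bead
        would coincide with the first across the periodic axial boundary
        (L an exact multiple of the spacing) it is dropped."""
        n = int(math.floor(self.bundle_length / self.core_bead_spacing)) + 1
        if (n - 1) * self.core_bead_spacing >= self.bundle_length - 1e-9:
            n -= 1
        return n

    @classmethod
    def for_domains(cls, n_domains: int, **kwargs) -> "GeometryParams":
        """Geometry whose length is n_domains design domains (42 bp each)."""
        return cls(bundle_length=n_domains * DOMAIN_LENGTH_NM, **kwargs)


@dataclass(frozen=True)
class BrushParams:
    """Bead-spring parameters of one brush chemistry."""

    kind: BrushKind
    bond_length: float       # nm
    bead_charge: float       # e
    bead_radius: float       # nm
    bending_kappa: float     # k_BT/rad^2 (0 = freely jointed)
    units_per_bead: float    # nt (SS) or bp (DS) represented by one bead
    bond_k: float = 100.0    # k_BT/nm^2

    def n_beads_for_contour(self, contour_nm: float) -> int:
        """Bead count whose contour (n * bond_length) best matches contour_nm."""
        return max(1, round(contour_nm / self.bond_length))

    def n_beads_for_bases(self, n_bases: float) -> int:
        return max(1, math.ceil(n_bases / self.units_per_bead))


#: polyT single strand: freely jointed beyond excluded volume, weakly charged.
SS_BRUSH = BrushParams(BrushKind.SS, bond_length=1.5, bead_charge=-0.75,
                       bead_radius=0.5, bending_kappa=0.0, units_per_bead=3)
#: hybridized duplex brush: stiff (kappa*b ~ 50 nm persistence) and strongly charged.
DS_BRUSH = BrushParams(BrushKind.DS, bond_length=1.0, bead_charge=-1.5,
                       bead_radius=0.5, bending_kappa=50.0, units_per_bead=3)

_BRUSH_BY_KIND = {BrushKind.SS: SS_BRUSH, BrushKind.DS: DS_BRUSH}
_BRUSH_SPECIES = {BrushKind.SS: Species.SS_BEAD, BrushKind.DS: Species.DS_BEAD}


def brush_params(kind: BrushKind) -> BrushParams:
    try:
        return _BRUSH_BY_KIND[kind]
    except KeyError:
        raise ValueError(f"no brush parameters for kind {kind}") from None


def build_core(geometry: GeometryParams, center_xy: Sequence[float] = (0.0, 0.0)) -> CGTopology:
    """Six straight fixed bead strings on the helix ring, one chain per helix."""
    topo = CGTopology()
    nz = geometry.beads_per_helix
    z = np.arange(nz) * geometry.core_bead_spacing
    for h in range(N_HELICES):
        ang = 2.0 * math.pi * h / N_HELICES
        cx = center_xy[0] + geometry.helix_ring_radius * math.cos(ang)
        cy = center_xy[1] + geometry.helix_ring_radius * math.sin(ang)
        pos = np.column_stack([np.full(nz, cx), np.full(nz, cy), z])
        topo.add_beads(Species.CORE, pos, geometry.core_charge,
                       geometry.helix_radius, chain_id=h, fixed=True)
    return topo


def _anchor_bead_index(topo: CGTopology, geometry: GeometryParams, site: GraftSite) -> int:
    """Core bead on the site's helix nearest the site's axial position."""
    nz = geometry.beads_per_helix
    iz = int(round(site.axial_position / geometry.core_bead_spacing))
    iz = min(max(iz, 0), nz - 1)
    return site.helix_index * nz + iz


def attach_brushes(
    topo: CGTopology,
    sites: Sequence[GraftSite],
    n_beads: int,
    kind: BrushKind,
    seed: int = 0,
    geometry: Optional[GeometryParams] = None,
    box: Optional[BoxSpec] = None,
    params: Optional[BrushParams] = None,
) -> List[GraftSite]:
    """Graft one bead-spring chain per site onto the core (in place).

    Initial conformations are straight rays pointing radially outward from
    the anchor's helix axis, with a small seeded angular perturbation so that
    chains are not exactly degenerate.  Returns the sites with their
    ``anchor_bead`` fields resolved.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if geometry is None:
        raise ValueError("attach_brushes requires the core geometry")
    bp = params or brush_params(kind)
    species = _BRUSH_SPECIES[kind]
    rng = np.random.default_rng(seed)
    center = box.center()[:2] if box is not None else np.zeros(2)

    resolved: List[GraftSite] = []
    for site in sites:
        anchor = _anchor_bead_index(topo, geometry, site)
        apos = topo.position[anchor]
        radial = apos[:2] - center
        nr = np.linalg.norm(radial)
        direction = np.array([radial[0] / nr, radial[1] / nr, 0.0])
        # small seeded tilt so chains start distinguishable but still ray-like
        tilt = rng.normal(scale=0.05, size=3)
        direction = direction + tilt
        direction /= np.linalg.norm(direction)
        # the chain grafts surface-to-surface: the anchor bond rest length is
        # the core/bead contact distance so the first bead clears the
        # excluded volume of the anchor's axial neighbours
        graft_r0 = geometry.helix_radius + bp.bead_radius
        offsets = (graft_r0 + np.arange(n_beads) * bp.bond_length)[:, None] * direction[None, :]
        pos = apos[None, :] + offsets
        if box is not None:
            wrapped = pos.copy()
            pz = box.periodic
            for ax in range(3):
                if pz[ax]:
                    wrapped[:, ax] %= box.lengths[ax]
            if not box.contains(wrapped):
                raise GeometryError(
                    f"brush chain at site {site.site_id} would leave the box; "
                    "enlarge the box or shorten the chain"
                )
            pos = wrapped
        idx = topo.add_beads(species, pos, bp.bead_charge, bp.bead_radius, fixed=False)
        topo.add_bonds([(anchor, idx[0])], graft_r0, bp.bond_k)
        if n_beads > 1:
            topo.add_bonds(np.column_stack([idx[:-1], idx[1:]]), bp.bond_length, bp.bond_k)
        if bp.bending_kappa > 0 and n_beads >= 3:
            # angles within the grafted chain only: the chain pivots freely
            # at the anchor (a short flexible linker joins brush and origami)
            triples = np.column_stack([idx[:-2], idx[1:-1], idx[2:]])
            topo.add_angles(triples, math.pi, bp.bending_kappa)
        resolved.append(GraftSite(site.site_id, site.domain_index, site.helix_index,
                                  site.axial_position, anchor_bead=anchor))
    return resolved


def _random_fill(
    topo: CGTopology,
    species: Species,
    count: int,
    box: BoxSpec,
    min_separation: float,
    charge: float,
    radius: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> None:
    """Uniform random insertion with a minimum-separation constraint."""
    if count == 0:
        return
    existing = topo.position
    placed = np.empty((0, 3))
    new_pos = []
    for _ in range(count):
        ok = False
        for _try in range(max_tries):
            cand = rng.random(3) * box.lengths
            ref = np.vstack([existing, placed]) if len(existing) + len(placed) else None
            if ref is not None and len(ref):
                d = ref - cand[None, :]
                for ax in range(3):
                    if box.periodic[ax]:
                        L = box.lengths[ax]
                        d[:, ax] -= L * np.round(d[:, ax] / L)
                if np.min(np.einsum("ij,ij->i", d, d)) < min_separation ** 2:
                    continue
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place {species.name} bead after {max_tries} tries; "
                "box too crowded for the requested min_separation"
            )
        placed = np.vstack([placed, cand])
        new_pos.append(cand)
    topo.add_beads(species, np.asarray(new_pos), charge, radius, fixed=False)


def place_precursors(
    topo: CGTopology,
    count: int,
    box: BoxSpec,
    min_separation: float = 1.0,
    seed: int = 0,
    charge: float = 1.0,
    radius: float = 0.5,
) -> CGTopology:
    """Insert cationic precursor beads uniformly at random (in place).

    Identical (topology, box, seed) gives identical placements.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = np.random.default_rng(seed)
    _random_fill(topo, Species.PRECURSOR, count, box, min_separation, charge, radius, rng)
    return topo


def counterion_count(conc_mM: float, box: BoxSpec) -> int:
    """Closed-form particle count for a concentration in the box volume."""
    return int(round(conc_mM / 1000.0 * box.volume_litres * AVOGADRO))


def add_salt(
    topo: CGTopology,
    mono_mM: float,
    di_mM: float,
    box: BoxSpec,
    seed: int = 0,
    min_separation: float = 0.5,
) -> CGTopology:
    """Add explicit salt ions plus neutralizing counterions (in place).

    Cation counts follow concentration x box volume; monovalent ions of the
    appropriate sign are then added so the total system charge is exactly
    zero (the last ion carries any fractional remainder).
    """
    if mono_mM < 0 or di_mM < 0:
        raise ValueError("salt concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    n_mono = counterion_count(mono_mM, box)
    n_di = counterion_count(di_mM, box)
    if n_mono:
        _random_fill(topo, Species.ION_MONO, n_mono, box, min_separation, +1.0, 0.3, rng)
    if n_di:
        _random_fill(topo, Species.ION_DI, n_di, box, min_separation, +2.0, 0.35, rng)
    q = topo.total_charge()
    if abs(q) > 1e-9:
        sign = -1.0 if q > 0 else 1.0
        n_full = int(math.floor(abs(q)))
        frac = abs(q) - n_full
        if n_full:
            _random_fill(topo, Species.ION_MONO, n_full, box, min_separation, sign, 0.3, rng)
        if frac > 1e-9:
            _random_fill(topo, Species.ION_MONO, 1, box, min_separation, sign * frac, 0.3, rng)
    return topo


def default_box(geometry: GeometryParams, brush_contour: float, box_xy: Optional[float] = None) -> BoxSpec:
    """Reflecting-wall x/y, periodic z box around the bundle.

    The radial half-width is at least core surface + 2x brush contour length
    so chains never reach the walls.
    """
    min_xy = 2.0 * (geometry.core_surface_radius + 2.0 * brush_contour)
    xy = max(box_xy or 0.0, min_xy)
    return BoxSpec([xy, xy, geometry.bundle_length],
                   [Boundary.REFLECTING, Boundary.REFLECTING, Boundary.PERIODIC])


@dataclass
class BuiltSystem:
    """A ready-to-simulate system with its provenance."""

    topo: CGTopology
    box: BoxSpec
    geometry: GeometryParams
    spec: BrushLayoutSpec
    sites: List[GraftSite]
    seed: int
    brush: Optional[BrushParams] = None


def build_system(
    layout: BrushLayoutSpec,
    geometry: Optional[GeometryParams] = None,
    brush_contour: float = 12.0,
    n_precursors: int = 50,
    seed: int = 0,
    box_xy: Optional[float] = None,
    mono_mM: float = 0.0,
    di_mM: float = 0.0,
    explicit_ions: bool = False,
    precursor_min_separation: float = 1.7,
) -> BuiltSystem:
    """Assemble core + brushes + precursors (+ optional explicit ions).

    Sub-seeds for brush jitter, precursor placement and ion placement are
    derived deterministically from ``seed``.
    """
    if geometry is None:
        geometry = GeometryParams.for_domains(layout.n_domains)
    topo = build_core(geometry)
    box = default_box(geometry, brush_contour if layout.n_modified else 0.0, box_xy)
    # the core was built around (0,0); move it to the box centre
    topo.position[:, 0] += box.center()[0]
    topo.position[:, 1] += box.center()[1]

    ss = np.random.SeedSequence(seed)
    s_brush, s_prec, s_ion = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]

    sites: List[GraftSite] = []
    bp = None
    if layout.n_modified:
        bp = brush_params(layout.brush_kind)
        n_beads = bp.n_beads_for_contour(brush_contour)
        sites = enumerate_graft_sites(layout, geometry.bundle_length)
        sites = attach_brushes(topo, sites, n_beads, layout.brush_kind,
                               seed=s_brush, geometry=geometry, box=box, params=bp)
    place_precursors(topo, n_precursors, box, precursor_min_separation, seed=s_prec)
    if explicit_ions and (mono_mM > 0 or di_mM > 0):
        add_salt(topo, mono_mM, di_mM, box, seed=s_ion)
    topo.validate()
    return BuiltSystem(topo, box, geometry, layout, sites, seed, bp)
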