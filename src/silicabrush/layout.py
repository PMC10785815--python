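"""Brush-layout notation for the six-helix bundle (6HB).

The 6HB is divided along its axis into equal design domains (27 in the
original design, one per 42 bp of duplex).  Each domain offers six initiator
positions, one per helix.  A layout string describes which domains carry
brushes using a run-length notation::

    6HB                 bare bundle
    6HB-27*-SS          all 27 domains modified, single-stranded brushes
    6HB-5*/17/5*-DS     5 modified / 17 bare / 5 modified, double-stranded

A trailing ``*`` marks a modified segment; the suffix gives the brush kind.
Reduced graft densities keep a site in every k-th modified domain per helix
(k = 1, 2, 3, 4 corresponding to 42, 84, 126 and 168 bp same-helix spacing).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Sequence, Tuple

__all__ = [
    "BrushKind",
    "BrushLayoutSpec",
    "GraftSite",
    "LayoutError",
    "parse_layout",
    "format_layout",
    "enumerate_graft_sites",
    "graft_sites_to_csv",
]

N_HELICES = 6

#: Allowed graft-density factors and the matching same-helix initiator
#: spacing in base pairs (k * 42 bp).
DENSITY_FACTORS = (1, 2, 3, 4)


class LayoutError(ValueError):
    """A layout string is well-formed but violates a design constraint."""


class BrushKind(Enum):
    NONE = "NONE"
    SS = "SS"
    DS = "DS"


_LAYOUT_RE = re.compile(
    r"^6HB(?:-(?P<segs>\d+\*?(?:/\d+\*?)*))?(?:-(?P<kind>SS|DS))?$"
)


@dataclass(frozen=True)
class BrushLayoutSpec:
    """Parsed layout: ordered segments of (domain_count, modified)."""

    n_domains: int
    segments: Tuple[Tuple[int, bool], ...]
    brush_kind: BrushKind
    density_factor: int = 1

    def __post_init__(self) -> None:
        if self.n_domains <= 0:
            raise LayoutError("n_domains must be positive")
        if self.density_factor not in DENSITY_FACTORS:
            raise LayoutError(
                f"density_factor must be one of {DENSITY_FACTORS}, "
                f"got {self.density_factor}"
            )
        if any(c <= 0 for c, _ in self.segments):
            raise LayoutError("segment domain counts must be positive")
        total = sum(c for c, _ in self.segments)
        if total != self.n_domains:
            raise LayoutError(
                f"segment domain counts sum to {total}, expected {self.n_domains}"
            )
        any_mod = any(mod for _, mod in self.segments)
        if any_mod and self.brush_kind is BrushKind.NONE:
            raise LayoutError("modified domains ('*') require an SS or DS suffix")
        if not any_mod and self.brush_kind is not BrushKind.NONE:
            raise LayoutError("SS/DS suffix given but no domain is modified")

    @property
    def modified_domains(self) -> Tuple[int, ...]:
        """1-based indices of modified domains, in axial order."""
        out: List[int] = []
        idx = 1
        for count, mod in self.segments:
            if mod:
                out.extend(range(idx, idx + count))
            idx += count
        return tuple(out)

    @property
    def n_modified(self) -> int:
        return len(self.modified_domains)

    @property
    def modified_fraction(self) -> float:
        return self.n_modified / self.n_domains

    def with_kind(self, kind: BrushKind) -> "BrushLayoutSpec":
        return BrushLayoutSpec(self.n_domains, self.segments, kind, self.density_factor)


def parse_layout(name: str, n_domains: int = 27, density_factor: int = 1) -> BrushLayoutSpec:
    """Parse a layout string such as ``"6HB-5*/17/5*-DS"``.

    ``n_domains`` is the total domain count the segment sum must match;
    bare ``"6HB"`` maps to a single unmodified segment of that length.
    """
    m = _LAYOUT_RE.match(name.strip())
    if m is None:
        raise LayoutError(f"cannot parse layout name {name!r}")
    segs = m.group("segs")
    kind = BrushKind(m.group("kind")) if m.group("kind") else BrushKind.NONE
    if segs is None:
        segments: Tuple[Tuple[int, bool], ...] = ((n_domains, False),)
    else:
        segments = tuple(
            (int(tok.rstrip("*")), tok.endswith("*")) for tok in segs.split("/")
        )
    return BrushLayoutSpec(n_domains, segments, kind, density_factor)


def format_layout(spec: BrushLayoutSpec) -> str:
    """Canonical layout string for a spec (inverse of :func:`parse_layout`)."""
    if not any(mod for _, mod in spec.segments):
        return "6HB"
    body = "/".join(f"{c}{'*' if mod else ''}" for c, mod in spec.segments)
    return f"6HB-{body}-{spec.brush_kind.value}"


@dataclass(frozen=True)
class GraftSite:
    """One brush-initiator position on the bundle surface."""

    site_id: int
    domain_index: int  # 1-based
    helix_index: int   # 0..5
    axial_position: float  # nm from the bundle end
    anchor_bead: int = -1  # filled in by the system builder


def enumerate_graft_sites(spec: BrushLayoutSpec, bundle_length: float) -> List[GraftSite]:
    """Enumerate graft sites for a layout on a bundle of the given length.

    Domains are equal axial slices; sites sit at domain centres.  At density
    factor k each helix keeps a site in every k-th modified domain, with the
    starting domain staggered across helices so that the total count is
    exactly ``6 * n_modified / k`` whenever that is an integer (and the
    same-helix spacing is k domains, i.e. k*42 bp, everywhere).
    Ordering is deterministic: by (domain_index, helix_index).
    """
    if bundle_length <= 0:
        raise ValueError("bundle_length must be positive")
    k = spec.density_factor
    domain_length = bundle_length / spec.n_domains
    sites: List[GraftSite] = []
    site_id = 0
    for pos_in_seq, dom in enumerate(spec.modified_domains):
        axial = (dom - 0.5) * domain_length
        for helix in range(N_HELICES):
            if (pos_in_seq + helix) % k != 0:
                continue
            sites.append(GraftSite(site_id, dom, helix, axial))
            site_id += 1
    return sites


def graft_sites_to_csv(sites: Sequence[GraftSite]) -> str:
    """Render sites as CSV text (site_id, domain_index, helix_index, axial_position_nm)."""
    buf = io.StringIO()
    buf.write("site_id,domain_index,helix_index,axial_position_nm\n")
    for s in sites:
        buf.write(f"{s.site_id},{s.domain_index},{s.helix_index},{s.axial_position:.6f}\n")
    return buf.getvalue()
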