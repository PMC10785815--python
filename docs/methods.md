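# Methods

## The system

Silica growth on DNA origami proceeds through cationic silane precursors
(TMAPS, co-condensing with TEOS) that adsorb electrostatically onto the
negatively charged DNA surface before the sol–gel network forms.  Grafting
DNA brushes onto a six-helix-bundle (6HB) origami changes where the
precursors go: stiff, strongly charged double-stranded (DS) brushes recruit
and retain precursors near the template, while flexible, weakly charged
single-stranded polyT (SS) brushes barely perturb it.  `silicabrush`
implements a coarse-grained model of exactly this competition, together
with the analyses used to quantify it, and a worm-like-chain estimator for
the persistence length of traced filaments (the stiffness read-out used for
silicified bundles on a surface).

## Coarse-grained model

**Template.**  The 6HB core is a rigid template: six straight strings of
fixed beads whose centres sit on a 2.0 nm ring.  With a 1.0 nm helix radius
the envelope diameter is exactly 6.0 nm.  One core bead represents 2 bp
(0.68 nm rise) and carries −1.0 e — the Manning-renormalized effective
charge of 4 phosphates (condensation fraction ≈ 0.24).  The bundle length is
an integer number of 42-bp design domains (14.28 nm each); a full-length
bundle has 27 domains.  Each domain offers six initiator positions, one per
helix, at the domain centre — the intra-domain initiator geometry is a
declared convention, since only the 42-bp same-helix spacing is fixed by
the design.  When the bundle length is an exact multiple of the bead
spacing, the final bead of each helix would coincide with the first across
the periodic axial boundary and is dropped.

**Brushes.**  A brush chain is a bead–spring polymer grafted
surface-to-surface at its initiator site (anchor bond rest length = helix
radius + bead radius):

| species | maps to | bond (nm) | charge (e) | bending κ (k_BT/rad²) |
|---------|---------|-----------|-----------|------------------------|
| SS bead | 3 nt    | 1.5       | −0.75     | 0 (freely jointed)     |
| DS bead | 3 bp    | 1.0       | −1.5      | 50 (L_p ≈ 50 nm)       |

SS parameters encode a flexible polyelectrolyte at roughly half the duplex
linear charge density; DS parameters give a chain far stiffer than its
contour, i.e. a charged rod.  At equal contour length a DS chain carries 3×
the total charge of an SS chain — brush selectivity in the model comes only
from charge and geometry, never from species-specific adhesion.

**Precursors and salt.**  Precursors are +1 e, 0.5 nm-radius beads
(TMAPS/TEOS treated as one cationic particle).  Salt is implicit by
default: a Debye screening length λ_D = 0.304 nm/√I, with I = c_mono +
3 c_di (mol/L).  The working buffer is 5 mM Mg²⁺, giving λ_D = 2.48 nm.
An explicit-ion mode (monovalent and divalent beads plus exact
neutralization) exists for mechanistic studies of ion competition.

**Interactions.**  In k_BT units:

* harmonic bonds (k = 100 k_BT/nm²) and harmonic angles;
* WCA excluded volume between all pairs, with σ chosen so the repulsion
  vanishes exactly at the sum of bead radii;
* screened Coulomb ℓ_B q_i q_j exp(−r/λ_D)/r with ℓ_B = 0.71 nm,
  switched smoothly (XPLOR C¹ switch) between 0.9×cutoff and the 5 nm
  pair cutoff (≈ 2 λ_D at the working salt);
* a short-range attractive well between precursors and all DNA beads —
  the attractive branch of a WCA-split Lennard-Jones, depth
  `attraction_epsilon`, reaching 1 nm beyond contact and switched to zero
  there.  This well is the effective stand-in for the silane condensation
  chemistry; its depth is the **single calibrated scalar** of the model
  (calibrated once on the DS system's condensation enhancement and then
  frozen for every other analysis).  The same depth applies to core, SS
  and DS beads.

Precursor–precursor attraction (untemplated nucleation) is off by default
and available behind a flag.

## Dynamics

Overdamped position-Langevin (Brownian) steps
x ← x + (dt/γ)F + √(2 k_BT dt/γ) ξ, with Stokes-like friction
γ = 2 × bead radius (so a precursor has D = 1 nm²/τ) and dt = 0.001 τ.
Fixed template beads are never moved.  Two numerical guards make the WCA
core safe at this step size: a deterministic zero-noise quench (500 steps
at dt/10) relaxes build-time overlaps before production, and the
deterministic part of each step is clamped at 0.2 nm — the clamp can only
engage several k_BT inside an excluded-volume core, where the equilibrium
weight is negligible, and prevents Euler overshoot through the steep
repulsion.  A step whose total displacement exceeds 1 nm raises an
instability error.  dt = 0.001 τ sits under the overdamped-Euler stability
bound for the stiffest thermally visited pair mode (two mobile beads at
WCA-rim curvature ≈ 10³ k_BT/nm²); 0.002 τ and above were observed to
diverge.

Forces come from a cell-list neighbour structure (skin 1 nm, rebuild when
any mobile bead has moved > skin/2) with per-pair charge products, contact
distances and well depths cached at rebuild time.  The kernel path is
cross-checked in the tests against an independent O(N²) reference to
1e-10 relative.  All noise flows through one seeded NumPy generator;
identical (system, parameters, seed) reproduce bit-identical trajectories
on a single thread.

## Study conditions (what the default experiment is)

The default condensation experiment — used by the tests, the CLI and
`scripts/acceptance.py` — is a desk-scale rendering of the brush-layout
comparison:

* full 27-domain 5*/17/5* layout (brush fraction 10/27 of the 385.6 nm
  bundle), ~3.4k core beads, 60 brush chains;
* equal-contour brushes of 9 nm (SS 6 beads, DS 9 beads) — far shorter
  than the experimental few-hundred-base brushes, but preserving the
  charge-density and stiffness contrast that drives the mechanism;
* 150 precursors in a 45 × 45 × 385.6 nm box (≈ 0.3 mM, the order of the
  experimental precursor concentration), reflecting walls radially and a
  periodic axis so precursor number is conserved — higher loads were found
  to wash out the brush/bare contrast because the precursors' own diffuse
  counterion atmosphere screens the brush field;
* 50 000 steps (50 τ) per replica, frames every 500 steps, analyses over
  the trailing half of each trajectory; five seeds per condition.

A precursor counts as *condensed* when its centre lies within
r_condense = 1.5 nm (contact) of any core bead centre; it is attributed to
the axial region (half-open intervals) of its nearest core bead.  The
headline *enhancement* is the percent excess of condensed precursors per
nm of brush region over the bare region.  Replicas are combined by pooling
the per-length densities across seeds before taking the ratio (a mean of
per-seed ratios is unstable when single seeds have few condensed
precursors in the denominator region); the quoted uncertainty is a
leave-one-seed-out jackknife.  Because the condensation radius is a
modelling choice, headline numbers are accompanied by a ±0.25 nm
sensitivity check.

*Residence events*: a precursor is "in the brush" while within
r_near = 1.2 nm of any brush bead; excursions up to `grace` frames do not
terminate an event.  *Radial charge profiles* histogram brush-bead charge
against distance from the bundle axis, time-averaged over the analysis
window.  *Probe scans* place a +1 test charge at contact with the core
surface (radius 3.5 nm from the axis) at the six helix azimuths and a grid
of axial positions, and average its screened-Coulomb energy over
decorrelated late frames; only DNA beads contribute, isolating the field
of the template.  The *Mg²⁺ sweep* recomputes λ_D per level (implicit
mode) on a smaller fully brushed 9-domain bundle and reports steady-window
condensed totals.

## Worm-like-chain estimator

Contours are resampled to equal arc-length steps; the tangent correlation
obeys ⟨cos θ(s)⟩ = exp(−s/2L_p) in the 2D (surface-equilibrated AFM)
convention, exp(−s/L_p) in 3D.  L_p is fit on log⟨cos θ⟩ vs s over
s ≤ contour/2 by generalized least squares: correlations at different
separations share the same slow bending modes of a finite ensemble, so
their errors are strongly correlated, and ordinary (even weighted) least
squares lets the redundant mid-range separations out-vote the precise
short ones — at the 100×L_p sample sizes used for validation this produces
15–20% seed-level errors.  GLS whitens with the empirical across-chain
covariance (shrunk 30% toward its diagonal, mapped to log scale by the
delta method), with the intercept fixed at the theoretical zero for
noise-free contours; observed recovery error is ≤ 4–5% for
L_p ∈ {50, 555, 1000} nm.  For contours resampled from bead-level or noisy
traces, chord averaging adds a positive offset to the log correlation, and
``fit_intercept=True`` frees the intercept to absorb it (simulated
bead-chains recover 52 nm at a 50 nm target with it, 62 nm without).
Uncertainty is a bootstrap over chains.  Effectively straight input
returns a 10⁶ nm sentinel.  Single-chain input falls back to a
through-origin weighted fit.

## What the generator does and does not emulate

The synthetic systems reproduce the *mechanistic* ingredients: rigid
hexagonal template geometry, the SS/DS contrast in stiffness and linear
charge density at matched contour and graft sites, screened electrostatics
at the working ionic strength, and a generic short-range
precursor–template adhesion.  They do not model silica network formation
(no precursor–precursor bonding), brush lengths at experimental scale
(9 nm vs hundreds of nm), hydrolysis/condensation kinetics, sequence
effects, hydrodynamics, or origami flexibility.  Passing tests therefore
support the *relative* brush-chemistry effects (DS vs SS vs bare ordering,
screening trends), not absolute rates or shell thicknesses.

## Numerical and design choices

* Scaled-down protocol sizes (system, steps, seeds) were chosen so a full
  replica set runs on a laptop-class single core in minutes per seed;
  they are part of the declared study conditions above.
* Switching functions make energy and force exactly continuous at every
  cutoff; closed-form checks are made below the switch-on radius.
* Region boundaries are half-open; assignment is by nearest core bead —
  deterministic tie-breaking.
* Enhancement uses per-unit-length densities because the 5*/17/5* brush
  and bare regions have unequal lengths.
* The equilibration window (first half) is reported in trajectory
  metadata rather than assumed converged; condensation is still slowly
  accumulating at the end of a replica, as in the underlying experiments.
* `attraction_epsilon = 1.4 k_BT` is the frozen calibrated value (chosen
  once so the pooled five-seed DS enhancement sits at the headline ~54%
  level, then frozen for every other analysis); all other parameters were
  fixed a priori by the mappings above.

## Known limitations

* Per-seed enhancement ratios remain noisy (tens of percentage points)
  because a replica holds only ~20 condensed precursors whose spatial
  pattern decorrelates slowly; the pooled-density estimator and five-seed
  jackknife quantify, but do not remove, this.  Raising the precursor load
  or extending the window does not help (the contrast itself degrades, and
  the condensed pattern is quasi-frozen within a replica).
* At the desk-scale brush length the model does not reproduce a strong
  retention contrast between brush chemistries: with a common condensation
  well, per-bead electrostatics differ by only ~0.35 k_BT, and brush-
  proximity residence times come out nearly equal for SS and DS.  Likewise
  the surface probe scan yields a ~1 k_BT DS-vs-bare attraction excess
  with the Manning-renormalized charge set, roughly half of what a
  bare-charge parameterization would give.  Both are properties of the
  declared parameterization, reported as measured.
* The implicit-salt Debye length treats Mg²⁺ only as screening; the
  competitive-binding part of the magnesium effect is only available via
  the explicit-ion mode.
* The rigid-core assumption suppresses any coupling between brush forces
  and bundle deformation.
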