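# silicabrush

Coarse-grained Brownian-dynamics simulation and analysis of silica-precursor
condensation on DNA-brush-functionalized six-helix-bundle (6HB) DNA origami,
plus a worm-like-chain persistence-length estimator for traced filaments.

## The problem

Growing a silica shell on DNA origami (Stöber-type chemistry with the
cationic silane TMAPS and TEOS) protects the structure, but bare origami
cross-link and aggregate during growth.  Grafting DNA brushes onto the
origami changes the picture: flexible single-stranded polyT brushes (SS)
sterically protect the template, and converting them to stiff, strongly
charged double-stranded brushes (DS) actively *recruits* precursors to the
brush-bearing regions.  This package implements the coarse-grained model
behind that mechanism for users who want to simulate and quantify it:

* a rigid 6HB template — six fixed bead strings on a 2 nm ring (6 nm
  envelope), one bead per 2 bp at the Manning-renormalized charge −1 e;
* brush chains grafted at layout-designed sites (`6HB-5*/17/5*-DS` style
  run-length notation; 27 domains × 6 positions, 42 bp same-helix spacing);
  SS beads are flexible and weakly charged (−0.75 e / 3 nt), DS beads stiff
  (L_p ≈ 50 nm) and strongly charged (−1.5 e / 3 bp);
* cationic precursor particles in implicit salt — Debye–Hückel
  electrostatics (λ_D = 0.304 nm/√I; 2.48 nm at the working 5 mM Mg²⁺),
  WCA excluded volume, and one calibrated short-range precursor–DNA well
  standing in for the condensation chemistry;
* overdamped Langevin dynamics (k_BT units, seeded and bit-reproducible),
  with analyses for regional condensation densities (the brush-vs-bare
  *enhancement*), residence times, radial brush charge profiles,
  surface probe-energy scans and [Mg²⁺] sweeps.

The worm-like-chain module (`silicabrush.wlc`) generates 2D/3D discrete
WLC contours and estimates persistence length from tangent correlations,
⟨cos θ(s)⟩ = exp(−s/2L_p) (2D surface convention), via a GLS fit validated
by parameter recovery — the analysis used to show silica-coated bundles
stiffen (555 → ~834 → ~1054 nm with growing shell thickness).

## Worked example

```python
from silicabrush.pipeline import DEFAULT_CONFIG, condensation_run

run = condensation_run(DEFAULT_CONFIG.with_layout("6HB-5*/17/5*-DS"), seed=0)
res = run.result
print(f"condensed on brush regions : {res.rho_brush:.4f} /nm")
print(f"condensed on bare region   : {res.rho_bare:.4f} /nm")
print(f"enhancement                : {res.enhancement_percent:.1f} %")
```

prints (seed 0, frozen defaults):

```
condensed on brush regions : 0.0980 /nm
condensed on bare region   : 0.0571 /nm
enhancement                : 71.7 %
```

i.e. in this replica the double-stranded-brush regions hold ~72% more
condensed precursor per nanometre of bundle than the bare middle section.
Pooled over five seeds the DS enhancement is ≈50% (jackknife SE ≈ 20
points) while the same frozen parameters give only ≈6% for single-stranded
brushes — the brush-chemistry contrast the model exists to capture.
Per-seed values scatter widely (a replica holds only ~20 condensed
precursors), which is why headline numbers are always pooled over seeds.
The equivalent CLI:

```bash
silicabrush init-config              # writes silicabrush.toml
silicabrush build "6HB-5*/17/5*-DS"  # topology -> PDB/JSON/CSV
silicabrush simulate --seed 0        # one trajectory -> XYZ + CSV
silicabrush analyze                  # replica set -> summary.json
silicabrush sweep --levels 5,16      # [Mg2+] screening sweep
silicabrush wlc --lp 555 --n-chains 30 --contour 1000 --step 5
```

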