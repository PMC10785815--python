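"""Physical constants and unit conventions.

Units used throughout the package:

* length — nanometres (nm)
* energy — thermal energy k_BT at the simulation temperature
* charge — elementary charges (e)
* time   — reduced Brownian time tau (set by the friction scale; a bead of
  unit friction has diffusion constant 1 nm^2/tau)
* concentration — millimolar (mM) at the user interface, mol/L internally
"""

from __future__ import annotations

import math

from scipy import constants as _sc

#: Avogadro's number (1/mol).
AVOGADRO = _sc.Avogadro

#: Gas constant in kcal/(mol K).
R_KCAL = _sc.R / _sc.calorie / 1000.0

#: Bjerrum length of water at 298 K (nm): distance at which two unit charges
#: interact with exactly 1 k_BT.
BJERRUM_WATER_298K = 0.71

#: Debye-length prefactor for water at 298 K: lambda_D = 0.304 nm / sqrt(I [mol/L]).
DEBYE_PREFACTOR_298K = 0.304

#: Reference temperature (K).
T_REF = 298.0

#: Helical rise of B-DNA (nm per base pair).
RISE_PER_BP = 0.34

#: Same-helix spacing between neighbouring brush initiators at full graft
#: density; one design domain of the six-helix bundle spans this many base pairs.
DOMAIN_BP = 42

#: Axial length of one design domain (nm).
DOMAIN_LENGTH_NM = DOMAIN_BP * RISE_PER_BP


def thermal_energy_kcal_per_mol(temperature: float = T_REF) -> float:
    """k_BT expressed in kcal/mol (0.59 kcal/mol at 298 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature


def ionic_strength_molar(mono_mM: float, di_mM: float) -> float:
    """Ionic strength I = 1/2 sum c_i z_i^2 in mol/L.

    ``mono_mM`` is a fully dissociated 1:1 salt (e.g. NaCl); ``di_mM`` a 2:1
    salt (e.g. MgCl2), contributing the divalent cation plus two monovalent
    anions, so I = c_mono + 3 c_di.
    """
    if mono_mM < 0 or di_mM < 0:
        raise ValueError("salt concentrations must be non-negative")
    return (mono_mM + 3.0 * di_mM) / 1000.0


def debye_length_nm(mono_mM: float, di_mM: float, temperature: float = T_REF) -> float:
    """Debye screening length (nm) for the given salt mixture.

    Uses lambda_D = 0.304 nm / sqrt(I) at 298 K.  The temperature dependence
    enters through sqrt(epsilon(T) k_B T); the solvent dielectric constant is
    held at its 298 K value, so only the explicit sqrt(T/298) factor is applied.
    """
    ionic = ionic_strength_molar(mono_mM, di_mM)
    if ionic <= 0:
        raise ValueError("Debye length undefined: no screening ions (I = 0)")
    return DEBYE_PREFACTOR_298K / math.sqrt(ionic) * math.sqrt(temperature / T_REF)
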