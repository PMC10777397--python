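"""Physical constants and unit conventions.

Internal unit system: length in Å, energy in kJ/mol, mass in amu (g/mol),
charge in elementary charges.  The derived time unit is then
``1 Å * sqrt(amu / (kJ/mol)) = 100 fs``, so a 10 fs MD timestep is 0.1
internal time units.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _c

#: Boltzmann constant on a molar scale, kJ/(mol K).
KB = _c.R / 1000.0

#: Coulomb prefactor e^2 * N_A / (4 pi eps0), in kJ Å / (mol e^2).
#: U(r) = COULOMB_K * q1 * q2 / (eps_r * r[Å])  ->  kJ/mol.
COULOMB_K = (_c.e**2 * _c.N_A / (4.0 * np.pi * _c.epsilon_0)) * 1e10 / 1000.0

#: One internal time unit in femtoseconds.
TIME_UNIT_FS = 100.0

#: kcal/mol in kJ/mol.
KCAL = _c.calorie  # 4.184

#: Dielectric constant of bulk water used for Debye screening lengths.
WATER_DIELECTRIC = 80.0


def debye_kappa(ionic_strength: float, temperature: float,
                dielectric: float = WATER_DIELECTRIC) -> float:
    """Inverse Debye screening length κ in Å⁻¹.

    κ² = 2 N_A e² I / (ε₀ ε_r k_B T) with the ionic strength ``I`` in mol/L.
    The dielectric here is the *solvent* dielectric setting the screening
    length of the mobile-ion atmosphere (water, 80, by default); it is held
    fixed when an effective medium dielectric is scanned as an energy
    prefactor elsewhere.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 0.0
    conc = ionic_strength * 1000.0 * _c.N_A  # ions / m^3
    kappa_sq = 2.0 * conc * _c.e**2 / (
        _c.epsilon_0 * dielectric * _c.k * temperature)
    return float(np.sqrt(kappa_sq) * 1e-10)  # 1/m -> 1/Å
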