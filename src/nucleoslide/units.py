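"""Internal unit conventions and physical constants.

Everything inside the package uses Angstrom for lengths, degrees for
angles, and kBT at the simulation temperature (default 300 K) for
energies.  These helpers convert to/from laboratory units and provide
the electrostatic length scales used by the Debye-Hueckel term.
"""

from __future__ import annotations

import numpy as np
from scipy import constants

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0

#: kB*T at 300 K expressed in kcal/mol.
KBT_300_KCAL_MOL = 0.5961


def kbt_in_kcal_mol(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kB*T in kcal/mol at the given temperature."""
    return constants.R / (constants.calorie * 1000.0) * temperature


def kcal_mol_to_kbt(energy_kcal: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an energy in kcal/mol to kBT units."""
    return energy_kcal / kbt_in_kcal_mol(temperature)


def permittivity_empirical(temperature: float, ionic_strength: float) -> float:
    """Temperature- and salt-dependent relative permittivity of water.

    Empirical solvent model used by three-site-per-nucleotide DNA
    forcefields: a quadratic temperature factor times a cubic salt
    correction, with the monovalent ionic strength in mol/L.
    """
    t_fac = 249.4 - 0.788 * temperature + 7.2e-4 * temperature**2
    c = ionic_strength
    s_fac = 1.0 - 0.2551 * c + 5.151e-2 * c**2 - 6.889e-3 * c**3
    return t_fac * s_fac


def bjerrum_length(temperature: float, eps_r: float) -> float:
    """Bjerrum length in Angstrom: e^2 / (4 pi eps0 eps_r kB T)."""
    lb_m = constants.e**2 / (
        4.0 * np.pi * constants.epsilon_0 * eps_r * constants.k * temperature
    )
    return lb_m * 1e10


def debye_length(temperature: float, eps_r: float, ionic_strength: float) -> float:
    """Debye screening length in Angstrom for a monovalent salt.

    ``ionic_strength`` is in mol/L.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    n = ionic_strength * 1000.0 * constants.N_A  # ions per m^3 (each species)
    kappa_sq = 2.0 * n * constants.e**2 / (
        constants.epsilon_0 * eps_r * constants.k * temperature
    )
    return 1e10 / np.sqrt(kappa_sq)
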