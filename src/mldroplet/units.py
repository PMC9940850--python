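"""Physical constants and unit conversions used throughout the package.

Internal unit system (the common coarse-grained MD convention):
length nm, energy kJ/mol, mass g/mol (Da), time ps.  Densities are
handled in two representations -- number density [nm^-3] and mass
density [mg/mL] -- linked through the chain (or bead) molar mass.
Surface tensions are quoted in mN/m externally and converted to
kT/nm^2 for use inside free-energy expressions.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1 (molar gas constant / 1000).
KB_KJ_PER_MOL_K: float = 0.008314462618

#: Boltzmann constant, J/K (per molecule).
KB_J_PER_K: float = 1.380649e-23

#: Unified atomic mass unit in mg scaled for the Da.nm^-3 -> mg/mL conversion:
#: 1 Da/nm^3 = 1.66054 mg/mL.
DA_PER_NM3_TO_MG_PER_ML: float = 1.66053906892

#: Coulomb constant in MD units, kJ mol^-1 nm e^-2 (1/(4 pi eps0)).
COULOMB_KJ_NM_PER_E2: float = 138.935458


def kT_kJ_per_mol(temperature: float) -> float:
    """Thermal energy kT in kJ/mol at the given temperature [K]."""
    return KB_KJ_PER_MOL_K * temperature


def number_density_to_mg_per_ml(rho_nm3: float | np.ndarray, molar_mass_da: float):
    """Convert a number density [nm^-3] to a mass density [mg/mL]."""
    return rho_nm3 * molar_mass_da * DA_PER_NM3_TO_MG_PER_ML


def mg_per_ml_to_number_density(rho_mgml: float | np.ndarray, molar_mass_da: float):
    """Convert a mass density [mg/mL] to a number density [nm^-3]."""
    return rho_mgml / (molar_mass_da * DA_PER_NM3_TO_MG_PER_ML)


def surface_tension_to_kT_per_nm2(sigma_mn_per_m: float, temperature: float) -> float:
    """Convert a surface tension from mN/m to kT/nm^2 at temperature [K].

    1 mN/m = 1e-3 J/m^2 = 1e-21 J/nm^2; at 300 K this is ~0.24143 kT/nm^2.
    """
    return sigma_mn_per_m * 1e-21 / (KB_J_PER_K * temperature)


def surface_tension_from_kT_per_nm2(sigma_kt_nm2: float, temperature: float) -> float:
    """Inverse of :func:`surface_tension_to_kT_per_nm2` (returns mN/m)."""
    return sigma_kt_nm2 * (KB_J_PER_K * temperature) / 1e-21
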