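"""Physical constants, unit conversions and element data.

All quantities used across the package are expressed in a fixed internal
unit system: energies in kcal/mol, lengths in Angstrom, masses in amu
(unified atomic mass units), angles in degrees, frequencies in cm^-1,
moments of inertia in amu*Angstrom^2 and temperatures in Kelvin.
Everything here derives from CODATA values as shipped with scipy.
"""

from __future__ import annotations

import scipy.constants as _sc

# --- fundamental constants (SI) ---------------------------------------------
H_PLANCK = _sc.h                      # J s
HBAR = _sc.hbar                       # J s
KB = _sc.k                            # J / K
N_AVOGADRO = _sc.N_A                  # 1 / mol
C_LIGHT_CM = _sc.c * 100.0            # cm / s
AMU_KG = _sc.atomic_mass              # kg

# --- unit conversions --------------------------------------------------------
KCAL_TO_J = _sc.calorie * 1000.0      # J per kcal (thermochemical calorie)
KCALMOL_TO_J = KCAL_TO_J / N_AVOGADRO        # J per (kcal/mol)
KB_KCALMOL = KB / KCALMOL_TO_J               # kB in kcal/mol/K  (~1.9872e-3)
# 1 kcal/mol expressed as a wavenumber:  E = h c nu~
KCALMOL_TO_WAVENUMBER = KCALMOL_TO_J / (H_PLANCK * C_LIGHT_CM)   # ~349.75 cm^-1/(kcal/mol)
WAVENUMBER_TO_KCALMOL = 1.0 / KCALMOL_TO_WAVENUMBER

# Mass-weighted Hessian eigenvalue [kcal/mol / (amu A^2)] -> angular
# frequency squared [s^-2]
MWHESS_EIG_TO_OMEGA2 = KCALMOL_TO_J / (AMU_KG * 1e-20)

# Moment of inertia amu*A^2 -> kg m^2
AMUA2_TO_KGM2 = AMU_KG * 1e-20

# --- element data ------------------------------------------------------------
# Covalent radii (Angstrom), Cordero et al. single-bond values; C is sp3.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "I": 1.39,
}

# Standard atomic weights (amu), IUPAC conventional values.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Br": 79.904, "I": 126.904,
}


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Angstrom; raises ``KeyError`` naming unknown symbols."""
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}") from None


def atomic_mass(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {symbol!r}") from None


def omega2_to_wavenumber(eigenvalue: float) -> float:
    """Signed conversion of a mass-weighted Hessian eigenvalue to cm^-1.

    Negative eigenvalues (imaginary modes) map to negative wavenumbers,
    keeping the sign available to the minimum/saddle discrimination.
    """
    import math

    omega2 = eigenvalue * MWHESS_EIG_TO_OMEGA2
    omega = math.sqrt(abs(omega2))
    nu = omega / (2.0 * math.pi * C_LIGHT_CM)
    return nu if omega2 >= 0 else -nu
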