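"""Physical constants and unit conversions used throughout the package.

Internal unit system: energies in kJ mol⁻¹, lengths in Å, masses in amu,
wavenumbers in cm⁻¹, dipole derivatives in D Å⁻¹.  Everything that leaves
this convention does so through a named constant defined here.
"""

from __future__ import annotations

import math

import scipy.constants as _sc

#: Molar gas constant, J mol⁻¹ K⁻¹ (CODATA 2018 exact value).
R_J_PER_MOL_K = 8.314462618
#: Molar gas constant, kJ mol⁻¹ K⁻¹.
R_KJ_PER_MOL_K = R_J_PER_MOL_K / 1000.0

#: Planck constant, J s.
H_PLANCK = _sc.h
#: Speed of light, cm s⁻¹ (wavenumber convention).
C_CM_PER_S = _sc.c * 100.0
#: Boltzmann constant, J K⁻¹.
K_BOLTZMANN = _sc.k
#: Avogadro constant, mol⁻¹.
N_AVOGADRO = _sc.N_A
#: Atomic mass unit, kg.
AMU_KG = _sc.atomic_mass

#: hc/k in cm·K — converts cm⁻¹ to a characteristic temperature.
HC_OVER_K_CM_K = H_PLANCK * C_CM_PER_S / K_BOLTZMANN
#: N_A·h·c in kJ mol⁻¹ cm — converts cm⁻¹ to molar energy.
WAVENUMBER_TO_KJ_PER_MOL = N_AVOGADRO * H_PLANCK * C_CM_PER_S / 1000.0

#: Hartree in kJ mol⁻¹ — applied only when ingesting external energy ledgers.
HARTREE_TO_KJ_PER_MOL = _sc.value("Hartree energy") * N_AVOGADRO / 1000.0

#: 1 atm in Pa.
ATM_PA = _sc.atm

#: Debye in C·m.
DEBYE_CM = 1e-21 / _sc.c

# Mass-weighted Hessian eigenvalue (kJ mol⁻¹ Å⁻² amu⁻¹) → angular frequency
# squared (s⁻²): λ·1000/(N_A·amu·Å²).
_LAMBDA_TO_OMEGA_SQ = 1000.0 / (N_AVOGADRO * AMU_KG * 1e-20)


def eigenvalue_to_wavenumber(lam: float) -> float:
    """Convert a mass-weighted Hessian eigenvalue (kJ mol⁻¹ Å⁻² amu⁻¹) to a
    harmonic wavenumber in cm⁻¹; negative eigenvalues map to negative
    (imaginary-mode) wavenumbers."""
    omega = math.sqrt(abs(lam) * _LAMBDA_TO_OMEGA_SQ)
    nu = omega / (2.0 * math.pi * C_CM_PER_S)
    return nu if lam >= 0 else -nu


def wavenumber_to_eigenvalue(nu: float) -> float:
    """Inverse of :func:`eigenvalue_to_wavenumber`."""
    lam = (2.0 * math.pi * C_CM_PER_S * abs(nu)) ** 2 / _LAMBDA_TO_OMEGA_SQ
    return lam if nu >= 0 else -lam


#: IR intensity conversion: km mol⁻¹ per (D Å⁻¹)² amu⁻¹ of squared
#: dipole-derivative projection |∂μ/∂Q|².  Derived from
#: A = N_A·π/(3·c²·4πε₀)·|∂μ/∂Q|² expressed in SI and rescaled; the
#: dimensional-analysis oracle test recomputes it from scipy.constants.
IR_INT_KM_PER_MOL = (
    N_AVOGADRO
    * math.pi
    / (3.0 * _sc.c**2 * 4.0 * math.pi * _sc.epsilon_0)
    * (DEBYE_CM / 1e-10) ** 2
    / AMU_KG
    / 1000.0
)

#: Standard temperature (K) and pressure (atm) for Boltzmann populations.
T_STANDARD_K = 298.15
P_STANDARD_ATM = 1.0
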