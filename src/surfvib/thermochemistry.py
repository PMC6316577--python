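"""Harmonic-oscillator / rigid-rotor statistical thermodynamics and
counterpoise-corrected reaction energetics.

Adsorbed species are treated as immobile: their thermal functions contain
vibrational terms only, computed from the fragment frequencies.  Gas-phase
species (the free molecule and its dimer) get the full RRHO treatment —
Sackur–Tetrode translation, classical rigid rotor with symmetry number, and
the same harmonic vibrational sums.  Interaction energies are corrected for
basis-set superposition error with the counterpoise method, optionally
including fragment deformation terms.  Reaction deltas are plain
products-minus-reactants bookkeeping; negative means bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from . import constants as K
from .model_io import CounterpoiseLedger

__all__ = [
    "ThermoState",
    "GasSpecies",
    "ReactionDelta",
    "vibrational_thermo",
    "gas_rrho",
    "adsorbed_thermo",
    "counterpoise",
    "reaction_delta",
]


@dataclass(frozen=True)
class ThermoState:
    """Thermal functions of one species at (T, P); energies kJ mol⁻¹,
    entropies kJ mol⁻¹ K⁻¹.

    ``E`` is the electronic (potential-energy) reference the thermal terms
    are added to; for relative bookkeeping it may be 0.  ``H`` and ``G`` are
    totals; the identity G = H − T·S is maintained by construction.
    """

    T: float
    P: float
    E: float
    ZPE: float
    U_vib: float
    S_vib: float
    U_trans: float = 0.0
    S_trans: float = 0.0
    U_rot: float = 0.0
    S_rot: float = 0.0
    PV: float = 0.0  # RT for an ideal gas, 0 for an immobile adsorbate

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        for name in ("S_vib", "S_trans", "S_rot", "ZPE"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be non-negative")

    @property
    def S(self) -> float:
        return self.S_vib + self.S_trans + self.S_rot

    @property
    def U(self) -> float:
        return self.E + self.U_vib + self.U_trans + self.U_rot

    @property
    def H(self) -> float:
        return self.U + self.PV

    @property
    def G(self) -> float:
        return self.H - self.T * self.S


@dataclass(frozen=True)
class GasSpecies:
    """Gas-phase species for RRHO thermochemistry.

    ``inertia`` is the principal moments of inertia in amu Å² — an empty
    tuple for an atom, one value for a linear molecule, three for a
    nonlinear one.  ``symmetry`` is the rotational symmetry number.
    Frequencies in cm⁻¹ (all positive).
    """

    mass: float  # amu
    inertia: tuple[float, ...] = ()
    symmetry: int = 1
    frequencies: tuple[float, ...] = ()
    E: float = 0.0  # electronic reference, kJ mol⁻¹

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.symmetry < 1:
            raise ValueError("symmetry number must be ≥ 1")
        if len(self.inertia) not in (0, 1, 3):
            raise ValueError("inertia: give 0 (atom), 1 (linear) or 3 moments")
        if any(i <= 0 for i in self.inertia):
            raise ValueError("moments of inertia must be positive")


def vibrational_thermo(
    frequencies: Sequence[float], T: float
) -> tuple[float, float, float]:
    """Harmonic-oscillator vibrational thermodynamics.

    Returns ``(ZPE, U_vib, S_vib)`` in kJ mol⁻¹ (S in kJ mol⁻¹ K⁻¹), summed
    over modes: with x = hcν̃/kT,

        ZPE   = Σ N_A·hcν̃/2
        U_vib = ZPE + Σ R·T·x/(eˣ − 1)
        S_vib = Σ R·[x/(eˣ − 1) − ln(1 − e⁻ˣ)]

    Imaginary (negative) frequencies must be filtered by the caller.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    nu = np.asarray(list(frequencies), dtype=float)
    if nu.size == 0:
        return (0.0, 0.0, 0.0)
    if np.any(nu < 0):
        raise ValueError(
            "negative (imaginary) frequency passed to vibrational_thermo; "
            "filter imaginary modes upstream"
        )
    nu = nu[nu > 0]  # exactly-zero modes contribute nothing in the HO model
    if nu.size == 0:
        return (0.0, 0.0, 0.0)
    x = K.HC_OVER_K_CM_K * nu / T
    R = K.R_KJ_PER_MOL_K
    zpe = float(np.sum(K.WAVENUMBER_TO_KJ_PER_MOL * nu / 2.0))
    # x/(eˣ−1) written as x·e⁻ˣ/(1−e⁻ˣ): stable for large x (low T)
    emx = np.exp(-x)
    occ = x * emx / (1.0 - emx)
    u_thermal = float(np.sum(R * T * occ))
    s = float(np.sum(R * (occ - np.log1p(-emx))))
    return (zpe, zpe + u_thermal, s)


def adsorbed_thermo(frequencies: Sequence[float], T: float, E: float = 0.0) -> ThermoState:
    """Vibration-only thermal state of an immobile adsorbed species.

    Translational and rotational terms are undefined for a bound adsorbate in
    the fragment-frequency scheme and are set to zero; there is no PV term.
    """
    nu = [f for f in frequencies if f >= 0]
    if len(nu) != len(list(frequencies)):
        import logging

        logging.getLogger(__name__).warning(
            "imaginary modes excluded from adsorbed-species thermochemistry"
        )
    zpe, u_vib, s_vib = vibrational_thermo(nu, T)
    return ThermoState(T=T, P=K.P_STANDARD_ATM, E=E, ZPE=zpe, U_vib=u_vib,
                       S_vib=s_vib)


def gas_rrho(species: GasSpecies, T: float, P: float) -> ThermoState:
    """Full RRHO thermal state of an ideal-gas species.

    Translation by the Sackur–Tetrode closed form, rotation by the classical
    rigid rotor with symmetry number, vibration by :func:`vibrational_thermo`;
    H includes the PV = RT term.
    """
    if T <= 0 or P <= 0:
        raise ValueError("temperature and pressure must be positive")
    R = K.R_KJ_PER_MOL_K
    m_kg = species.mass * K.AMU_KG
    p_pa = P * K.ATM_PA
    # Sackur–Tetrode: S = R[ln(q_t) + 5/2], q_t = (2πmkT/h²)^{3/2}·kT/P
    q_trans = (2 * math.pi * m_kg * K.K_BOLTZMANN * T / K.H_PLANCK**2) ** 1.5 * (
        K.K_BOLTZMANN * T / p_pa
    )
    s_trans = R * (math.log(q_trans) + 2.5)
    u_trans = 1.5 * R * T
    # Rigid rotor (classical)
    amuA2 = K.AMU_KG * 1e-20
    if not species.inertia:
        s_rot = u_rot = 0.0
    elif len(species.inertia) == 1:
        I = species.inertia[0] * amuA2
        q_rot = 8 * math.pi**2 * I * K.K_BOLTZMANN * T / (
            species.symmetry * K.H_PLANCK**2
        )
        s_rot = R * (math.log(q_rot) + 1.0)
        u_rot = R * T
    else:
        Ia, Ib, Ic = (i * amuA2 for i in species.inertia)
        q_rot = (
            math.sqrt(math.pi * Ia * Ib * Ic)
            / species.symmetry
            * (8 * math.pi**2 * K.K_BOLTZMANN * T / K.H_PLANCK**2) ** 1.5
        )
        s_rot = R * (math.log(q_rot) + 1.5)
        u_rot = 1.5 * R * T
    zpe, u_vib, s_vib = vibrational_thermo(species.frequencies, T)
    return ThermoState(
        T=T, P=P, E=species.E, ZPE=zpe, U_vib=u_vib, S_vib=s_vib,
        U_trans=u_trans, S_trans=s_trans, U_rot=u_rot, S_rot=s_rot,
        PV=R * T,
    )


def counterpoise(ledger: CounterpoiseLedger, include_deformation: bool = True) -> float:
    """Counterpoise-corrected interaction energy (kJ mol⁻¹).

    ΔE^CP = E_complex − E_A^ghost − E_B^ghost
            + (E_A^own − E_A^relaxed) + (E_B^own − E_B^relaxed)

    The parenthesized deformation terms (energetic cost of distorting each
    fragment from its relaxed geometry to the in-complex one) are included
    by default; ``include_deformation=False`` drops them, leaving the pure
    BSSE-free interaction at fixed fragment geometries.
    """
    de = ledger.E_complex - ledger.E_fragA_ghost - ledger.E_fragB_ghost
    if include_deformation:
        de += (ledger.E_fragA_own - ledger.E_A_relaxed)
        de += (ledger.E_fragB_own - ledger.E_B_relaxed)
    return de


@dataclass(frozen=True)
class ReactionDelta:
    """ΔE, ΔH, ΔG (kJ mol⁻¹) of a reaction, products minus reactants."""

    dE: float
    dH: float
    dG: float
    reaction: str = ""


def _ehg(obj) -> tuple[float, float, float]:
    if isinstance(obj, ThermoState):
        return (obj.E, obj.H, obj.G)
    if hasattr(obj, "dE_c"):  # AdductEnergetics parts
        return (obj.dE_c, obj.dH_c, obj.dG_c)
    e, h, g = obj  # (E, H, G) triple
    return (float(e), float(h), float(g))


def reaction_delta(
    products: Iterable, reactants: Iterable, reaction: str = ""
) -> ReactionDelta:
    """ΔX = X_products − X_reactants for X = E, H, G.

    Accepts :class:`ThermoState` objects, (E, H, G) triples, or adduct
    ledger records on either side.  Negative deltas mean the products side
    is bound relative to the reactants.
    """
    pe = ph = pg = 0.0
    for p in products:
        e, h, g = _ehg(p)
        pe, ph, pg = pe + e, ph + h, pg + g
    re_ = rh = rg = 0.0
    for r in reactants:
        e, h, g = _ehg(r)
        re_, rh, rg = re_ + e, rh + h, rg + g
    return ReactionDelta(dE=pe - re_, dH=ph - rh, dG=pg - rg, reaction=reaction)
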