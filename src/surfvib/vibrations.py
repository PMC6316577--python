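"""Partial (reduced) Hessian vibrational analysis.

A fragment — typically the adsorbed molecule(s) plus the surface silanol
groups — is carved out of the full force-constant matrix by deleting the
rows and columns of all other atoms, which are thereby treated as fixed.
The mass-weighted fragment Hessian is diagonalized to give harmonic
frequencies and normal modes; IR intensities follow from projecting the
Cartesian dipole derivatives onto each mode.  Because the fragment is
embedded in a rigid environment, no translation/rotation projection is
applied: the six near-zero modes of a free molecule do not exist here.

Mode-class frequency scaling corrects harmonic C=O stretch and NH₂ bend
positions for anharmonicity with one multiplicative factor per class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import constants as K
from .model_io import ScaleRuleConfig

__all__ = [
    "FragmentHessian",
    "ModeSet",
    "ScaleRule",
    "reduce_hessian",
    "normal_modes",
    "ir_intensities",
    "apply_scaling",
    "DEFAULT_SCALE_RULES",
]

log = logging.getLogger(__name__)

ScaleRule = ScaleRuleConfig  # domain alias: rules live in model_io for serialization

#: Anharmonicity corrections for the amide modes: C=O stretch ×0.9972,
#: NH₂ bend ×1.0102 (experimental/harmonic frequency ratios of the free
#: molecule).  Windows are an implementation vehicle for assigning the class.
DEFAULT_SCALE_RULES: tuple[ScaleRule, ...] = (
    ScaleRule("CO_stretch", 1600.0, 1800.0, 0.9972),
    ScaleRule("NH2_bend", 1500.0, 1600.0, 1.0102),
)

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class FragmentHessian:
    """Force constants and dipole response of a vibrational fragment.

    ``H`` is the symmetric 3N×3N second-derivative matrix of the energy with
    respect to Cartesian displacements, in kJ mol⁻¹ Å⁻²; ``masses`` are the N
    fragment atomic masses in amu; ``dipole_derivatives`` is the optional
    3N×3 array ∂μ/∂x in D Å⁻¹.  ``fragment_atoms`` records which atoms of
    the parent structure the rows refer to.
    """

    H: np.ndarray
    masses: np.ndarray
    fragment_atoms: tuple[int, ...] = ()
    dipole_derivatives: np.ndarray | None = None

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        if m.ndim != 1 or m.size < 1:
            raise ValueError("need at least one fragment atom")
        n3 = 3 * m.size
        if H.shape != (n3, n3):
            raise ValueError(f"H must be {n3}x{n3} for {m.size} atoms")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
        scale = max(1.0, float(np.abs(H).max()))
        if np.abs(H - H.T).max() > _SYM_TOL * scale:
            raise ValueError("Hessian is not symmetric within tolerance")
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "masses", m)
        if self.dipole_derivatives is not None:
            dd = np.asarray(self.dipole_derivatives, dtype=float)
            if dd.shape != (n3, 3):
                raise ValueError(f"dipole_derivatives must be {n3}x3")
            object.__setattr__(self, "dipole_derivatives", dd)

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    def mass_weighted(self) -> np.ndarray:
        """M^(−1/2)·H·M^(−1/2), eigenvalues in kJ mol⁻¹ Å⁻² amu⁻¹."""
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(self.masses), 3)
        return self.H * np.outer(inv_sqrt_m, inv_sqrt_m)


@dataclass(frozen=True)
class ModeSet:
    """Harmonic modes of one fragment.

    ``frequencies`` are 3N wavenumbers in cm⁻¹, ascending, with imaginary
    modes encoded as negative values.  ``modes`` holds the mass-weighted
    orthonormal eigenvectors as columns.  ``intensities`` (km mol⁻¹),
    ``scaled_frequencies`` and per-mode ``scale_class`` labels are filled by
    :func:`ir_intensities` and :func:`apply_scaling`.
    """

    frequencies: np.ndarray
    modes: np.ndarray
    intensities: np.ndarray | None = None
    scaled_frequencies: np.ndarray | None = None
    scale_class: tuple[str | None, ...] = field(default=())

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        L = np.asarray(self.modes, dtype=float)
        if L.shape != (f.size, f.size):
            raise ValueError("modes must be square, one column per frequency")
        if np.any(np.diff(f) < 0):
            raise ValueError("frequencies must be sorted ascending")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "modes", L)
        if self.intensities is not None:
            ints = np.asarray(self.intensities, dtype=float)
            if ints.shape != f.shape:
                raise ValueError("one intensity per mode required")
            object.__setattr__(self, "intensities", ints)
        if self.scaled_frequencies is not None:
            sf = np.asarray(self.scaled_frequencies, dtype=float)
            if sf.shape != f.shape:
                raise ValueError("one scaled frequency per mode required")
            object.__setattr__(self, "scaled_frequencies", sf)
        if not self.scale_class:
            object.__setattr__(self, "scale_class", tuple([None] * f.size))

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    @property
    def real_frequencies(self) -> np.ndarray:
        return self.frequencies[self.frequencies >= 0]

    @property
    def effective_frequencies(self) -> np.ndarray:
        """Scaled frequencies if present, raw otherwise."""
        return (self.scaled_frequencies
                if self.scaled_frequencies is not None else self.frequencies)

    def to_frame(self):
        """Export as a pandas DataFrame (mode, ν, ν_scaled, intensity, class)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "mode": np.arange(self.n_modes),
                "frequency_cm-1": self.frequencies,
                "scaled_frequency_cm-1": self.effective_frequencies,
                "intensity_km_mol-1": (
                    self.intensities if self.intensities is not None
                    else np.full(self.n_modes, np.nan)
                ),
                "scale_class": [c or "" for c in self.scale_class],
            }
        )


def reduce_hessian(
    full_H: np.ndarray,
    fragment_atoms: Sequence[int],
    masses: Sequence[float],
    dipole_derivatives: np.ndarray | None = None,
) -> FragmentHessian:
    """Carve the fragment sub-block out of a full Hessian.

    ``full_H`` is 3N_total×3N_total over all atoms; ``masses`` has one entry
    per atom of the full system.  Environment atoms are treated as fixed:
    their rows and columns are deleted, not projected out.  Dipole
    derivatives, when given for the full system (3N_total×3), are sliced the
    same way.
    """
    idx = list(fragment_atoms)
    if not idx:
        raise ValueError("fragment must contain at least one atom")
    if len(set(idx)) != len(idx):
        raise ValueError("fragment atom indices must be unique")
    full_H = np.asarray(full_H, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n_total = masses.size
    if full_H.shape != (3 * n_total, 3 * n_total):
        raise ValueError("full_H shape inconsistent with masses")
    if any(i < 0 or i >= n_total for i in idx):
        raise ValueError("fragment atom index out of range")
    rows = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in idx])
    sub = full_H[np.ix_(rows, rows)]
    dd = None
    if dipole_derivatives is not None:
        dd = np.asarray(dipole_derivatives, dtype=float)[rows]
    return FragmentHessian(
        H=sub, masses=masses[idx], fragment_atoms=tuple(idx),
        dipole_derivatives=dd,
    )


def normal_modes(fh: FragmentHessian) -> ModeSet:
    """Diagonalize the mass-weighted fragment Hessian.

    Frequencies are ν̃ᵢ = √λᵢ/(2πc) for λᵢ ≥ 0 and −√(−λᵢ)/(2πc) otherwise
    (imaginary modes negative), sorted ascending.  Eigenvectors are the
    mass-weighted orthonormal normal modes.
    """
    mw = fh.mass_weighted()
    lam, L = np.linalg.eigh(mw)
    freqs = np.array([K.eigenvalue_to_wavenumber(v) for v in lam])
    order = np.argsort(freqs)
    return ModeSet(frequencies=freqs[order], modes=L[:, order])


def ir_intensities(fh: FragmentHessian, ms: ModeSet) -> ModeSet:
    """Attach IR intensities (km mol⁻¹) to a mode set.

    Intensity of mode i is proportional to |∂μ/∂Qᵢ|² where
    ∂μ/∂Qᵢ = Σ_k (∂μ/∂x_k)·(M^(−1/2)·Lᵢ)_k; the proportionality constant
    ``constants.IR_INT_KM_PER_MOL`` converts (D Å⁻¹)² amu⁻¹ to km mol⁻¹.
    Modes with zero dipole-derivative projection get exactly 0.
    """
    if fh.dipole_derivatives is None:
        raise ValueError(
            "fragment has no dipole derivatives; run the intensity-free "
            "workflow (normal_modes only) or supply ∂μ/∂x"
        )
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(fh.masses), 3)
    # (3,) dipole-derivative projection per mode: D^T (M^-1/2 L_i)
    proj = fh.dipole_derivatives.T @ (inv_sqrt_m[:, None] * ms.modes)
    intensities = K.IR_INT_KM_PER_MOL * np.sum(proj**2, axis=0)
    return replace(ms, intensities=intensities)


def apply_scaling(ms: ModeSet, rules: Sequence[ScaleRule] = DEFAULT_SCALE_RULES) -> ModeSet:
    """Apply mode-class frequency scaling.

    Each mode whose raw frequency falls inside a rule's window is multiplied
    by that rule's factor and labelled with its class; modes outside every
    window pass through unscaled.  Windows must not overlap (the class
    assignment would be ambiguous).
    """
    rules = list(rules)
    for i, a in enumerate(rules):
        for b in rules[i + 1:]:
            if a.lo < b.hi and b.lo < a.hi:
                raise ValueError(
                    f"scale windows {a.class_label!r} and {b.class_label!r} overlap"
                )
    scaled = ms.frequencies.copy()
    classes: list[str | None] = [None] * ms.n_modes
    for rule in rules:
        mask = (ms.frequencies >= rule.lo) & (ms.frequencies < rule.hi)
        scaled[mask] = ms.frequencies[mask] * rule.factor
        for j in np.nonzero(mask)[0]:
            classes[j] = rule.class_label
    return replace(ms, scaled_frequencies=scaled, scale_class=tuple(classes))
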