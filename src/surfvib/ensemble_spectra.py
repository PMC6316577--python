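"""Boltzmann ensembles of surface adducts and simulated IR spectra.

Competing adsorption structures equilibrate according to their interaction
Gibbs free energies: p_i = exp(−ΔG_i/RT)/Σ_j exp(−ΔG_j/RT).  Each adduct's
stick spectrum (scaled harmonic frequencies + IR intensities) is broadened
with Gaussians of fixed FWHM and the ensemble spectrum is the
population-weighted linear combination, optionally rescaled so its maximum
matches an experimental reference inside a chosen window.  Peak and
shoulder positions of (baseline-subtracted) traces are read off with
standard signal-processing tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from . import constants as K
from .model_io import AdductEnergetics, Spectrum
from .vibrations import ModeSet

__all__ = [
    "Ensemble",
    "SpectrumSynthesisParams",
    "boltzmann_populations",
    "round_half_up",
    "adduct_spectrum",
    "ensemble_spectrum",
    "normalize_to_reference",
    "baseline_and_peaks",
    "plot_overlay",
]

log = logging.getLogger(__name__)


def boltzmann_populations(
    dG: Sequence[float], T: float = K.T_STANDARD_K
) -> np.ndarray:
    """Equilibrium populations from Gibbs free energies (kJ mol⁻¹).

    Shift-stable: the minimum ΔG is subtracted before exponentiation, so the
    result is invariant under ΔG → ΔG + c and safe for large spreads.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    g = np.asarray(list(dG), dtype=float)
    if g.size == 0:
        raise ValueError("need at least one ΔG value")
    w = np.exp(-(g - g.min()) / (K.R_KJ_PER_MOL_K * T))
    return w / w.sum()


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero-ward ties upward, the convention used for
    printed population tables (e.g. 0.0060 → 0.01)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Ensemble:
    """A set of competing adducts of one coverage class with Boltzmann
    populations at temperature T."""

    members: tuple[AdductEnergetics, ...]
    T: float = K.T_STANDARD_K
    mode_sets: tuple[ModeSet | None, ...] = ()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        coverages = {m.coverage for m in self.members}
        if len(coverages) > 1:
            raise ValueError(
                "ensemble members must share one coverage class (LC xor HC), "
                f"got {sorted(coverages)}"
            )
        if not self.mode_sets:
            object.__setattr__(
                self, "mode_sets", tuple([None] * len(self.members))
            )
        elif len(self.mode_sets) != len(self.members):
            raise ValueError("one mode set (or None) per member required")

    @property
    def coverage(self) -> str:
        return self.members[0].coverage

    @property
    def populations(self) -> np.ndarray:
        return boltzmann_populations([m.dG_c for m in self.members], self.T)

    def population_table(self):
        """pandas DataFrame (name, ΔG, p) matching the printed-table layout."""
        import pandas as pd

        p = self.populations
        return pd.DataFrame(
            {
                "name": [m.name for m in self.members],
                "dG_c": [m.dG_c for m in self.members],
                "p": p,
                "p_rounded": [round_half_up(v) for v in p],
            }
        )


@dataclass(frozen=True)
class SpectrumSynthesisParams:
    """Gaussian band-shape parameters.

    ``fwhm`` in cm⁻¹ (20 by default); grid (lo, hi, step) in cm⁻¹; under the
    ``height`` amplitude convention each Gaussian's peak height equals the
    mode intensity, under ``area`` its integral does.
    """

    fwhm: float = 20.0
    grid_lo: float = 1500.0
    grid_hi: float = 1800.0
    grid_step: float = 0.5
    amplitude: str = "height"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not self.grid_lo < self.grid_hi:
            raise ValueError("grid requires lo < hi")
        if self.grid_step <= 0:
            raise ValueError("grid step must be positive")
        if self.amplitude not in ("height", "area"):
            raise ValueError("amplitude convention must be 'height' or 'area'")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def adduct_spectrum(ms: ModeSet, params: SpectrumSynthesisParams) -> Spectrum:
    """Gaussian-broadened stick spectrum of one adduct.

    Gaussians are centred at the scaled frequencies (raw ones if no scaling
    was applied); modes with non-positive or missing intensity contribute
    nothing.  A grid that excludes every mode yields a zero trace with a
    warning.
    """
    grid = params.grid
    trace = np.zeros_like(grid)
    centers = ms.effective_frequencies
    intensities = (
        ms.intensities if ms.intensities is not None
        else np.ones_like(centers)
    )
    sigma = params.sigma
    any_in = False
    for nu0, inten in zip(centers, intensities):
        if inten <= 0 or nu0 <= 0:
            continue
        if params.grid_lo - 4 * sigma <= nu0 <= params.grid_hi + 4 * sigma:
            any_in = True
        amp = inten if params.amplitude == "height" else inten / (
            sigma * math.sqrt(2 * math.pi)
        )
        trace += amp * np.exp(-((grid - nu0) ** 2) / (2 * sigma**2))
    if not any_in and centers.size:
        log.warning("no modes fall inside the spectral grid; trace is zero")
    return Spectrum(grid, trace, {"kind": "simulated", "fwhm": params.fwhm,
                                  "amplitude": params.amplitude})


def ensemble_spectrum(
    e: Ensemble,
    params: SpectrumSynthesisParams,
    population_threshold: float = 0.005,
) -> Spectrum:
    """Population-weighted ensemble spectrum Σᵢ pᵢ·Aᵢ(ν̃).

    Every member whose population exceeds ``population_threshold`` must
    carry a mode set; members below the threshold are silently omitted
    (nil components).
    """
    p = e.populations
    grid = params.grid
    trace = np.zeros_like(grid)
    for member, ms, pi in zip(e.members, e.mode_sets, p):
        if pi <= population_threshold:
            continue
        if ms is None:
            raise ValueError(
                f"member {member.name} has population {pi:.3f} > "
                f"{population_threshold} but no mode set"
            )
        trace += pi * adduct_spectrum(ms, params).absorbance
    return Spectrum(grid, trace, {"kind": "simulated", "fwhm": params.fwhm,
                                  "coverage": e.coverage,
                                  "amplitude": params.amplitude})


def normalize_to_reference(
    sim: Spectrum, exp: Spectrum, window: tuple[float, float]
) -> Spectrum:
    """Rescale a simulated trace so its maximum inside ``window`` equals the
    experimental maximum inside the same window."""
    lo, hi = window
    sim_mask = (sim.wavenumbers >= lo) & (sim.wavenumbers <= hi)
    exp_mask = (exp.wavenumbers >= lo) & (exp.wavenumbers <= hi)
    if not sim_mask.any() or not exp_mask.any():
        raise ValueError("window does not overlap both spectra")
    sim_max = float(sim.absorbance[sim_mask].max())
    if sim_max <= 0:
        raise ValueError("simulated spectrum has no positive maximum in window")
    exp_max = float(exp.absorbance[exp_mask].max())
    return sim.scaled(exp_max / sim_max,
                      normalization={"window": (lo, hi), "reference_max": exp_max})


def baseline_and_peaks(
    exp: Spectrum,
    window: tuple[float, float],
    prominence: float | None = None,
    band_fwhm: float = 20.0,
) -> tuple[Spectrum, dict[str, list[float]]]:
    """Linear-baseline subtraction and peak/shoulder reading in a window.

    A straight line through the trace values at the window endpoints is
    subtracted.  The corrected trace is Savitzky–Golay smoothed on a length
    scale of roughly half the expected band FWHM; maxima are local maxima
    of the smoothed trace above a prominence threshold (default: the larger
    of 5% of the corrected range and 6× the point-noise estimate).
    Shoulders — unresolved components riding on a band flank — are read as
    prominent minima of the smoothed second derivative that do not coincide
    with a detected maximum.

    Returns the baseline-subtracted spectrum (window only) and
    ``{"maxima": [...], "shoulders": [...]}`` in cm⁻¹.
    """
    lo, hi = window
    mask = (exp.wavenumbers >= lo) & (exp.wavenumbers <= hi)
    if mask.sum() < 5:
        raise ValueError("window must span at least 5 grid points")
    x = exp.wavenumbers[mask]
    y = exp.absorbance[mask]
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    corrected = y - (y[0] + slope * (x - x[0]))
    step = float(np.median(np.diff(x)))
    # smoothing window ≈ band_fwhm/2 in grid points, odd, ≥5, < n
    win = int(round(band_fwhm / 2.0 / step)) | 1
    win = max(5, min(win, (x.size - 1) | 1 if (x.size - 1) % 2 else x.size - 1))
    smooth = (savgol_filter(corrected, window_length=win, polyorder=3)
              if x.size > win else corrected)
    rng = float(smooth.max() - smooth.min())
    # featureless trace guard: amplitude at numerical-noise level
    significant = rng > 1e-10 * max(1.0, float(np.abs(y).max()))
    # robust point-noise estimate from first differences
    noise = float(np.std(np.diff(corrected))) / math.sqrt(2.0)
    if prominence is None:
        prominence = max(0.05 * rng, 6.0 * noise) if significant else np.inf
    idx, _ = find_peaks(smooth, prominence=prominence)
    maxima = [float(x[i]) for i in idx]
    shoulders: list[float] = []
    if significant and x.size > win:
        d2 = savgol_filter(corrected, window_length=win, polyorder=3, deriv=2)
        # curvature noise floor from the quiet (low-absorbance) region
        quiet = smooth < 0.1 * rng
        mad = (
            float(np.median(np.abs(d2[quiet] - np.median(d2[quiet])))) * 1.4826
            if quiet.any() else 0.0
        )
        thr = max(6.0 * mad, 1e-5 * float(np.ptp(d2)))
        d2_idx, _ = find_peaks(-d2, prominence=thr)
        for i in d2_idx:
            pos = float(x[i])
            if smooth[i] < 0.15 * rng:
                continue  # curvature dip in the baseline region
            if all(abs(pos - m) > band_fwhm / 2.0 for m in maxima):
                shoulders.append(pos)
    sub = Spectrum(x, corrected, {**exp.meta, "baseline": "linear",
                                  "window": (lo, hi)})
    return sub, {"maxima": maxima, "shoulders": shoulders}


def plot_overlay(
    spectra: Sequence[Spectrum], labels: Sequence[str], path: str
) -> None:
    """Write a simple overlay plot of experimental vs simulated traces."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s, lab in zip(spectra, labels):
        style = "o" if s.meta.get("kind") == "experimental" else "-"
        ax.plot(s.wavenumbers, s.absorbance, style, ms=2, label=lab)
    ax.set_xlabel("wavenumber / cm$^{-1}$")
    ax.set_ylabel("absorbance / a.u.")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
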