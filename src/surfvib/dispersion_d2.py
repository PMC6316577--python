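"""Grimme D2 pairwise dispersion for clusters and 2D-periodic slabs.

The D2 correction adds, for every atom pair, −s₆·C₆ᵢⱼ/r⁶ damped at short
range by the sigmoid f(r) = 1/(1 + exp(−d·(r/R_r − 1))) with R_r the sum of
the two elemental van der Waals radii and C₆ᵢⱼ the geometric mean of the
elemental coefficients.  For a slab the sum runs over in-plane lattice
translations out to a real-space cutoff.  Because the term is additive to
the electronic energy, the purely dispersive part of an interaction energy
is ΔE_disp = E_disp(complex) − E_disp(fragment A) − E_disp(fragment B),
which for fixed geometries equals the inter-fragment pair sum.

Default parameters are the published 2006 D2 set (C₆ in J nm⁶ mol⁻¹,
converted to kJ mol⁻¹ Å⁶ at load time) with the PBE global scale s₆ = 0.75,
stored in a versioned JSON data file and overridable by the user.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_io import Structure

__all__ = [
    "D2Params",
    "load_default_params",
    "pair_dispersion",
    "total_dispersion",
    "dispersion_component",
    "lattice_sum_convergence",
]

#: J nm⁶ mol⁻¹ → kJ mol⁻¹ Å⁶
_C6_UNIT = 1000.0

_MIN_SEPARATION = 0.1  # Å; closer atoms indicate a broken geometry


@dataclass(frozen=True)
class D2Params:
    """D2 parameter set: per-element C6 (kJ mol⁻¹ Å⁶) and vdW radius (Å),
    global scale s6, damping steepness d, real-space cutoff (Å)."""

    c6: dict[str, float]
    r0: dict[str, float]
    s6: float = 0.75
    d: float = 20.0
    cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.s6 <= 0 or self.d <= 0 or self.cutoff <= 0:
            raise ValueError("s6, d and cutoff must be positive")
        for el, v in self.c6.items():
            if v < 0:
                raise ValueError(f"C6[{el}] must be non-negative")
        for el, v in self.r0.items():
            if v <= 0:
                raise ValueError(f"r0[{el}] must be positive")

    def require(self, *elements: str) -> None:
        missing = [e for e in elements if e not in self.c6 or e not in self.r0]
        if missing:
            raise KeyError(
                f"no D2 parameters for {missing}; supported elements: "
                f"{sorted(set(self.c6) & set(self.r0))}"
            )


def load_default_params(path: str | Path | None = None) -> D2Params:
    """Load the packaged (or a user-supplied) JSON D2 parameter file."""
    if path is None:
        path = Path(__file__).parent / "data" / "d2_params.json"
    raw = json.loads(Path(path).read_text())
    elements = raw["elements"]
    return D2Params(
        c6={el: v["C6"] * _C6_UNIT for el, v in elements.items()},
        r0={el: v["r0"] for el, v in elements.items()},
        s6=raw.get("s6", 0.75),
        d=raw.get("d", 20.0),
        cutoff=raw.get("cutoff", 30.0),
    )


def pair_dispersion(elem_i: str, elem_j: str, r: float, params: D2Params) -> float:
    """Damped dispersion energy (kJ mol⁻¹) of one atom pair at distance r Å."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    params.require(elem_i, elem_j)
    c6 = math.sqrt(params.c6[elem_i] * params.c6[elem_j])
    rr = params.r0[elem_i] + params.r0[elem_j]
    f = 1.0 / (1.0 + math.exp(-params.d * (r / rr - 1.0)))
    return -params.s6 * c6 / r**6 * f


def _pair_energy_vec(
    sym_i: np.ndarray, sym_j: np.ndarray, r: np.ndarray, params: D2Params
) -> np.ndarray:
    c6i = np.array([params.c6[s] for s in sym_i])
    c6j = np.array([params.c6[s] for s in sym_j])
    rri = np.array([params.r0[s] for s in sym_i])
    rrj = np.array([params.r0[s] for s in sym_j])
    c6 = np.sqrt(c6i * c6j)
    rr = rri + rrj
    f = 1.0 / (1.0 + np.exp(-params.d * (r / rr - 1.0)))
    return -params.s6 * c6 / r**6 * f


def total_dispersion(s: Structure, params: D2Params | None = None) -> float:
    """Total D2 energy (kJ mol⁻¹) of a cluster or 2D-periodic slab.

    For a periodic structure the sum includes every image pair within the
    real-space cutoff; each unique pair is counted once (central-cell pairs
    i<j, plus one representative of every ±T image pair).
    """
    if params is None:
        params = load_default_params()
    params.require(*set(s.symbols))
    pos = s.positions
    sym = np.array(s.symbols)
    n = len(s)
    energy = 0.0
    # central cell, unique pairs
    if n > 1:
        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
        if np.any(d < _MIN_SEPARATION):
            raise ValueError("overlapping atoms (r < 0.1 Å) in structure")
        mask = d <= params.cutoff
        if mask.any():
            energy += float(np.sum(
                _pair_energy_vec(sym[ii[mask]], sym[jj[mask]], d[mask], params)
            ))
    if s.cell is None:
        return energy
    # periodic images: iterate translations T ≠ 0 over a half-space so each
    # image pair is counted once (pair (i, j+T) ≡ (j, i−T)).
    vecs = s.lattice_vectors()
    na = int(math.ceil(params.cutoff / np.linalg.norm(vecs[0]))) + 1
    nb = int(math.ceil(params.cutoff / np.linalg.norm(vecs[1]))) + 1
    for ka, kb in itertools.product(range(-na, na + 1), range(-nb, nb + 1)):
        if (ka, kb) == (0, 0) or (ka, kb) < (0, 0):
            continue  # lexicographic half-space
        T = ka * vecs[0] + kb * vecs[1]
        diff = pos[:, None, :] - pos[None, :, :] + T  # r_i - r_j - (-T)
        d = np.linalg.norm(diff.reshape(-1, 3), axis=1)
        if np.any(d < _MIN_SEPARATION):
            raise ValueError("overlapping atoms across periodic images")
        mask = d <= params.cutoff
        if not mask.any():
            continue
        si = np.repeat(sym, n)[mask]
        sj = np.tile(sym, n)[mask]
        energy += float(np.sum(_pair_energy_vec(si, sj, d[mask], params)))
    return energy


def dispersion_component(
    complex_s: Structure,
    fragA: Structure,
    fragB: Structure | None,
    params: D2Params | None = None,
    check: bool = True,
) -> float:
    """Dispersive part of the interaction energy (kJ mol⁻¹).

    ΔE_disp = E_disp(complex) − E_disp(A) − E_disp(B) with all geometries
    fixed at the complex geometry.  The fragments must partition the
    complex's atoms exactly; an empty second fragment (``None``) gives 0.
    When ``check`` is set the equivalent direct inter-fragment pair sum is
    computed as well and the two routes asserted equal — a guard against
    partition mistakes.
    """
    if params is None:
        params = load_default_params()
    if fragB is None:
        if len(fragA) != len(complex_s):
            raise ValueError("fragments must partition the complex's atoms")
        return 0.0
    if len(fragA) + len(fragB) != len(complex_s):
        raise ValueError("fragments must partition the complex's atoms")
    combined = sorted(
        (tuple(np.round(p, 8)), s)
        for p, s in zip(
            np.vstack([fragA.positions, fragB.positions]),
            fragA.symbols + fragB.symbols,
        )
    )
    whole = sorted(
        (tuple(np.round(p, 8)), s)
        for p, s in zip(complex_s.positions, complex_s.symbols)
    )
    if combined != whole:
        raise ValueError(
            "fragment atoms do not match the complex (overlap or missing atoms)"
        )
    de = (
        total_dispersion(complex_s, params)
        - total_dispersion(fragA, params)
        - total_dispersion(fragB, params)
    )
    if check and complex_s.cell is None:
        direct = _interfragment_sum(fragA, fragB, params)
        if not math.isclose(de, direct, rel_tol=1e-9, abs_tol=1e-9):
            raise AssertionError(
                f"dual-route dispersion mismatch: subtraction {de!r} vs "
                f"inter-fragment sum {direct!r}"
            )
    return de


def _interfragment_sum(fragA: Structure, fragB: Structure, params: D2Params) -> float:
    """Direct sum over inter-fragment pairs (non-periodic)."""
    if len(fragA) == 0 or len(fragB) == 0:
        return 0.0
    diff = fragA.positions[:, None, :] - fragB.positions[None, :, :]
    d = np.linalg.norm(diff.reshape(-1, 3), axis=1)
    mask = d <= params.cutoff
    if not mask.any():
        return 0.0
    si = np.repeat(np.array(fragA.symbols), len(fragB))[mask]
    sj = np.tile(np.array(fragB.symbols), len(fragA))[mask]
    return float(np.sum(_pair_energy_vec(si, sj, d[mask], params)))


def lattice_sum_convergence(
    s: Structure, params: D2Params | None = None,
    cutoffs: tuple[float, ...] = (20.0, 30.0, 40.0),
) -> dict[float, float]:
    """Total dispersion at a series of cutoffs — a convergence check utility
    for periodic slabs.  Returns {cutoff: energy}."""
    if params is None:
        params = load_default_params()
    out = {}
    for c in cutoffs:
        p = D2Params(c6=params.c6, r0=params.r0, s6=params.s6, d=params.d,
                     cutoff=c)
        out[c] = total_dispersion(s, p)
    return out
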