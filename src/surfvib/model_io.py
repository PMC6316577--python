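"""Core data model and readers/writers.

Containers for surface structures, adduct energy ledgers, IR spectra and run
configuration, plus plain-text I/O: extended XYZ with a 2D-cell comment line,
CSV energy tables in the ``ΔE^c (ΔE_disp) / ΔH^c / ΔG^c`` layout, two-column
CSV or JCAMP-DX spectra, and YAML/JSON run configs.

Energies are stored and exchanged in kJ mol⁻¹ throughout; conversion from
hartree happens only at ingestion via ``constants.HARTREE_TO_KJ_PER_MOL``.
Unicode minus signs (U+2212), as printed in typical journal tables, are
normalized to ASCII at parse time.
"""

from __future__ import annotations

import csv
import io
import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "Structure",
    "AdductEnergetics",
    "CounterpoiseLedger",
    "Spectrum",
    "RunConfig",
    "ScaleRuleConfig",
    "read_structure",
    "write_structure",
    "read_energy_table",
    "write_energy_table",
    "read_spectrum",
    "write_spectrum",
    "load_reference_tables",
    "ATOMIC_MASSES",
    "Role",
]

Role = Literal["adsorbate", "silanol", "framework", "terminal_H"]
_ROLES = {"adsorbate", "silanol", "framework", "terminal_H"}

# Standard atomic weights (amu), IUPAC 2021 abridged; ample for silica/organic
# adsorbate work.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "Fe": 55.845, "Zn": 65.38, "Br": 79.904, "I": 126.90,
}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _norm_minus(s: str) -> str:
    return s.replace("−", "-").replace("–", "-")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Structure:
    """Atoms with Cartesian coordinates (Å), an optional 2D cell and per-atom
    role tags.

    The cell is the (a, b, γ) triple of a 2D-periodic slab: in-plane lattice
    lengths in Å and the angle between them in degrees.  Roles distinguish the
    adsorbed molecule(s), the surface silanol groups, the silica framework and
    the fixed terminal hydrogens that cap the slab.
    """

    symbols: tuple[str, ...]
    positions: np.ndarray  # (N, 3) Å
    cell: tuple[float, float, float] | None = None  # (a, b, gamma°)
    roles: tuple[Role, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] == 0:
            raise ValueError("positions must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if len(self.symbols) != pos.shape[0]:
            raise ValueError("symbols and positions length mismatch")
        for s in self.symbols:
            if s not in ATOMIC_MASSES:
                raise ValueError(
                    f"unknown element symbol {s!r}; known: "
                    + ", ".join(sorted(ATOMIC_MASSES))
                )
        object.__setattr__(self, "positions", pos)
        roles = self.roles or tuple("framework" for _ in self.symbols)
        if len(roles) != len(self.symbols):
            raise ValueError("one role per atom required")
        for r in roles:
            if r not in _ROLES:
                raise ValueError(f"unknown role {r!r}; allowed: {sorted(_ROLES)}")
        object.__setattr__(self, "roles", tuple(roles))
        if self.cell is not None:
            a, b, gamma = self.cell
            if not (a > 0 and b > 0 and 0 < gamma < 180):
                raise ValueError("cell requires a > 0, b > 0, 0 < γ < 180")
            object.__setattr__(self, "cell", (float(a), float(b), float(gamma)))

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def masses(self) -> np.ndarray:
        """Atomic masses in amu, one per atom."""
        return np.array([ATOMIC_MASSES[s] for s in self.symbols])

    def lattice_vectors(self) -> np.ndarray:
        """2×3 in-plane lattice vectors (Å); raises if no cell is set."""
        if self.cell is None:
            raise ValueError("structure has no cell")
        a, b, gamma = self.cell
        g = math.radians(gamma)
        return np.array(
            [[a, 0.0, 0.0], [b * math.cos(g), b * math.sin(g), 0.0]]
        )

    def select(self, indices: Sequence[int]) -> "Structure":
        idx = list(indices)
        return Structure(
            symbols=tuple(self.symbols[i] for i in idx),
            positions=self.positions[idx],
            cell=self.cell,
            roles=tuple(self.roles[i] for i in idx),
        )


def read_structure(path: str | Path) -> Structure:
    """Read an extended XYZ file.

    Line 1 is the atom count; line 2 is a comment that may carry the 2D cell
    as ``cell="a b gamma"`` (or a bare ``a b gamma`` triple).  Atom lines are
    ``symbol x y z [role]``; atoms without a role tag default to framework.
    """
    path = Path(path)
    lines = _norm_minus(path.read_text()).splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: not an XYZ file (fewer than 2 lines)")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: first line must be the atom count") from exc
    if natoms < 1:
        raise ParseError(f"{path}: structures must be non-empty")
    comment = lines[1]
    cell = _parse_cell_comment(comment)
    symbols: list[str] = []
    positions: list[list[float]] = []
    roles: list[str] = []
    atom_lines = lines[2 : 2 + natoms]
    if len(atom_lines) < natoms:
        raise ParseError(f"{path}: expected {natoms} atom lines, got {len(atom_lines)}")
    for lineno, line in enumerate(atom_lines, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: malformed atom line {line!r}")
        sym = parts[0]
        if sym not in ATOMIC_MASSES:
            raise ParseError(f"{path}:{lineno}: unknown element symbol {sym!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed atom line {line!r}") from exc
        role = parts[4] if len(parts) > 4 else "framework"
        if role not in _ROLES:
            raise ParseError(f"{path}:{lineno}: unknown role tag {role!r}")
        symbols.append(sym)
        positions.append(xyz)
        roles.append(role)
    return Structure(tuple(symbols), np.array(positions), cell, tuple(roles))  # type: ignore[arg-type]


def _parse_cell_comment(comment: str) -> tuple[float, float, float] | None:
    m = re.search(r'cell\s*=\s*"?([-\d.eE\s]+)"?', comment)
    text = m.group(1) if m else comment
    parts = text.split()
    if len(parts) == 3:
        try:
            a, b, g = (float(p) for p in parts)
            return (a, b, g)
        except ValueError:
            return None
    return None


def write_structure(s: Structure, path: str | Path) -> None:
    """Write extended XYZ; inverse of :func:`read_structure`."""
    lines = [str(len(s))]
    if s.cell is not None:
        a, b, g = s.cell
        lines.append(f'cell="{a:.6f} {b:.6f} {g:.6f}"')
    else:
        lines.append("")
    for sym, pos, role in zip(s.symbols, s.positions, s.roles):
        lines.append(f"{sym} {pos[0]:.8f} {pos[1]:.8f} {pos[2]:.8f} {role}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Energy ledgers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdductEnergetics:
    """One surface adduct's counterpoise-corrected energy ledger (kJ mol⁻¹).

    ``dE_c`` is the BSSE-corrected interaction energy, ``dE_disp`` its
    pairwise-dispersion part (``None`` when not reported), ``dH_c`` and
    ``dG_c`` the interaction enthalpy and Gibbs free energy.  Negative means
    bound.  The electronic part may be repulsive, so ``|dE_disp| ≤ |dE_c|``
    is deliberately not enforced.
    """

    name: str
    coverage: Literal["LC", "HC"]
    topology: Literal["monomer", "double_monomer", "dimer"]
    dE_c: float
    dE_disp: float | None
    dH_c: float
    dG_c: float

    def __post_init__(self) -> None:
        if self.coverage not in ("LC", "HC"):
            raise ValueError(f"coverage must be LC or HC, got {self.coverage!r}")
        if self.topology not in ("monomer", "double_monomer", "dimer"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for label in ("dE_c", "dH_c", "dG_c"):
            v = getattr(self, label)
            if not math.isfinite(v):
                raise ValueError(f"{self.name}: {label} must be finite")
        if self.dE_disp is not None and not math.isfinite(self.dE_disp):
            raise ValueError(f"{self.name}: dE_disp must be finite or None")

    @property
    def dE_electronic(self) -> float:
        """Non-dispersive (electronic) part of the interaction energy."""
        if self.dE_disp is None:
            raise ValueError(f"{self.name}: dispersion component unavailable")
        return self.dE_c - self.dE_disp


_ENERGY_COLS = ("dE_c", "dH_c", "dG_c")


def read_energy_table(path: str | Path) -> list[AdductEnergetics]:
    """Read a CSV adduct energy table.

    Expected columns: ``name, coverage, topology, dE_c, dE_disp, dH_c, dG_c``.
    Alternatively ``dE_c`` may carry the dispersion part as a parenthetical,
    e.g. ``-80.5 (-27.4)``, in which case the ``dE_disp`` column may be
    absent.  A blank ``dE_disp`` marks the dispersion split as unavailable.
    """
    path = Path(path)
    text = _norm_minus(path.read_text())
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ParseError(f"{path}: empty file")
    fields = {f.strip() for f in reader.fieldnames}
    missing = {"name", "dE_c", "dH_c"} - fields
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "dG_c" not in fields:
        raise ParseError(
            f"{path}: missing dG_c column — Boltzmann populations are "
            "impossible without Gibbs free energies"
        )
    records: list[AdductEnergetics] = []
    for row in reader:
        row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
        name = row.get("name", "")
        de_raw = row.get("dE_c", "")
        m = re.match(r"^([-\d.eE+]+)\s*\(\s*([-\d.eE+]+)\s*\)\s*$", de_raw)
        try:
            if m:
                dE_c = float(m.group(1))
                dE_disp: float | None = float(m.group(2))
            else:
                dE_c = float(de_raw)
                disp_raw = row.get("dE_disp", "")
                dE_disp = float(disp_raw) if disp_raw else None
            dH_c = float(row["dH_c"])
            dG_c = float(row["dG_c"])
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: non-numeric energy in row {name!r}") from exc
        records.append(
            AdductEnergetics(
                name=name,
                coverage=row.get("coverage", "LC") or "LC",  # type: ignore[arg-type]
                topology=row.get("topology", "monomer") or "monomer",  # type: ignore[arg-type]
                dE_c=dE_c,
                dE_disp=dE_disp,
                dH_c=dH_c,
                dG_c=dG_c,
            )
        )
    if not records:
        raise ParseError(f"{path}: no data rows")
    return records


def write_energy_table(records: Iterable[AdductEnergetics], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "coverage", "topology", "dE_c", "dE_disp", "dH_c", "dG_c"])
        for r in records:
            w.writerow(
                [r.name, r.coverage, r.topology, r.dE_c,
                 "" if r.dE_disp is None else r.dE_disp, r.dH_c, r.dG_c]
            )


def load_reference_tables() -> tuple[list[AdductEnergetics], list[AdductEnergetics]]:
    """Load the bundled published energy ledgers for formamide on amorphous
    silica: 5 low-coverage (single-molecule) and 7 high-coverage (second
    adsorption) adducts, PBE-D2 counterpoise-corrected, in kJ mol⁻¹.

    Returns ``(lc_records, hc_records)``.
    """
    data_dir = Path(__file__).parent / "data"
    lc = read_energy_table(data_dir / "formamide_silica_lc.csv")
    hc = read_energy_table(data_dir / "formamide_silica_hc.csv")
    return lc, hc


# ---------------------------------------------------------------------------
# Counterpoise ledger
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CounterpoiseLedger:
    """Component energies (kJ mol⁻¹) for a counterpoise BSSE correction.

    Fragment energies at the complex geometry come in two flavours: in the
    full ghost-augmented basis (``*_ghost``) and in the fragment's own basis
    (``*_own``); ``E_A_relaxed``/``E_B_relaxed`` are the isolated relaxed
    fragments.  The variational bound ``E_ghost ≤ E_own`` must hold per
    fragment.
    """

    E_complex: float
    E_fragA_ghost: float
    E_fragB_ghost: float
    E_fragA_own: float
    E_fragB_own: float
    E_A_relaxed: float
    E_B_relaxed: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        tol = 1e-9 * max(1.0, abs(self.E_fragA_own), abs(self.E_fragB_own))
        if self.E_fragA_ghost > self.E_fragA_own + tol:
            raise ValueError(
                "fragment A ghost-basis energy above own-basis energy "
                "(violates the variational bound)"
            )
        if self.E_fragB_ghost > self.E_fragB_own + tol:
            raise ValueError(
                "fragment B ghost-basis energy above own-basis energy "
                "(violates the variational bound)"
            )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber grid (cm⁻¹, strictly increasing) with an absorbance trace.

    ``meta`` records provenance: ``kind`` (simulated or experimental), the
    Gaussian FWHM for simulated traces, and any normalization reference.
    Raw experimental traces may dip below zero; non-negativity is not
    enforced.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.shape != w.shape:
            raise ValueError("wavenumbers and absorbance must be equal-length 1D")
        if w.size < 2:
            raise ValueError("need at least 2 points to define a grid")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "meta", dict(self.meta))

    def scaled(self, factor: float, **meta) -> "Spectrum":
        return Spectrum(self.wavenumbers, self.absorbance * factor,
                        {**self.meta, **meta})


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum from two-column CSV or JCAMP-DX.

    Points are sorted by ascending wavenumber regardless of file order;
    duplicated abscissa values are an error.
    """
    path = Path(path)
    text = _norm_minus(path.read_text())
    if text.lstrip().startswith("##"):
        pairs = _parse_jcamp(text, path)
        kind = "experimental"
    else:
        pairs = _parse_two_column(text, path)
        kind = "experimental"
    if len(pairs) < 2:
        raise ParseError(f"{path}: need at least 2 points to define a grid")
    arr = np.array(pairs, dtype=float)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ParseError(f"{path}: duplicated wavenumber values in abscissa")
    return Spectrum(arr[:, 0], arr[:, 1], {"kind": kind, "source": str(path)})


def _parse_two_column(text: str, path: Path) -> list[tuple[float, float]]:
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s;]+", line)
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns")
        try:
            pairs.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1:  # tolerate a header row
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric data {line!r}")
    return pairs


def _parse_jcamp(text: str, path: Path) -> list[tuple[float, float]]:
    """Minimal JCAMP-DX reader for the ``(XY..XY)`` AFFN variant."""
    lines = text.splitlines()
    in_data = False
    pairs: list[tuple[float, float]] = []
    xfac = yfac = 1.0
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("##XFACTOR="):
            xfac = float(stripped.split("=", 1)[1])
        elif stripped.startswith("##YFACTOR="):
            yfac = float(stripped.split("=", 1)[1])
        elif stripped.startswith(("##XYDATA=", "##XYPOINTS=", "##PEAK TABLE=")):
            in_data = True
            continue
        elif stripped.startswith("##"):
            in_data = False
            continue
        elif in_data and stripped:
            for token in re.split(r"[;\s]+", stripped):
                if not token:
                    continue
                xy = token.split(",")
                if len(xy) != 2:
                    raise ParseError(f"{path}: malformed XY token {token!r}")
                pairs.append((float(xy[0]) * xfac, float(xy[1]) * yfac))
    if not pairs:
        raise ParseError(f"{path}: no XYDATA found in JCAMP-DX file")
    return pairs


def write_spectrum(s: Spectrum, path: str | Path, fmt: str | None = None) -> None:
    """Write a spectrum as CSV or JCAMP-DX (``(XY..XY)`` AFFN variant).

    ``fmt`` is ``"csv"`` or ``"jcamp"``; inferred from the suffix when None
    (``.jdx``/``.dx`` → JCAMP).
    """
    path = Path(path)
    if fmt is None:
        fmt = "jcamp" if path.suffix.lower() in (".jdx", ".dx") else "csv"
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["wavenumber_cm-1", "absorbance"])
            for x, y in zip(s.wavenumbers, s.absorbance):
                w.writerow([f"{x:.10g}", f"{y:.12g}"])
    elif fmt == "jcamp":
        lines = [
            "##TITLE=" + str(s.meta.get("title", "surfvib spectrum")),
            "##JCAMP-DX=4.24",
            "##DATA TYPE=INFRARED SPECTRUM",
            "##XUNITS=1/CM",
            "##YUNITS=ABSORBANCE",
            "##XFACTOR=1.0",
            "##YFACTOR=1.0",
            f"##FIRSTX={s.wavenumbers[0]:.10g}",
            f"##LASTX={s.wavenumbers[-1]:.10g}",
            f"##NPOINTS={len(s.wavenumbers)}",
            "##XYDATA=(XY..XY)",
        ]
        lines += [
            f"{x:.10g},{y:.12g}" for x, y in zip(s.wavenumbers, s.absorbance)
        ]
        lines.append("##END=")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleRuleConfig:
    """Serializable mode-scaling rule: multiply every harmonic frequency in
    ``(lo, hi)`` cm⁻¹ by ``factor``."""

    class_label: str
    lo: float
    hi: float
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("scale factor must be positive")
        if not self.lo < self.hi:
            raise ValueError("window requires lo < hi")


_DEFAULT_SCALE_RULES = (
    ScaleRuleConfig("CO_stretch", 1600.0, 1800.0, 0.9972),
    ScaleRuleConfig("NH2_bend", 1500.0, 1600.0, 1.0102),
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run parameters.

    Defaults mirror the study conditions for formamide on amorphous silica:
    standard temperature and pressure (298.15 K, 1 atm), 20 cm⁻¹ Gaussian
    FWHM, a 1500–1800 cm⁻¹ grid at 0.5 cm⁻¹ covering the amide C=O stretch
    and NH₂ bend, and the two anharmonicity scale factors for those mode
    classes (0.9972 and 1.0102).
    """

    temperature: float = 298.15  # K
    pressure: float = 1.0  # atm
    fwhm: float = 20.0  # cm⁻¹
    grid_lo: float = 1500.0
    grid_hi: float = 1800.0
    grid_step: float = 0.5
    scale_rules: tuple[ScaleRuleConfig, ...] = _DEFAULT_SCALE_RULES
    coverage: Literal["LC", "HC"] = "LC"
    amplitude: Literal["height", "area"] = "height"
    population_threshold: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.grid_step <= 0:
            raise ValueError("grid step must be positive")
        if not self.grid_lo < self.grid_hi:
            raise ValueError("grid requires lo < hi")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a mapping")
        rules = data.pop("scale_rules", None)
        if rules is not None:
            data["scale_rules"] = tuple(
                ScaleRuleConfig(**r) for r in rules
            )
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = {
            "temperature": self.temperature,
            "pressure": self.pressure,
            "fwhm": self.fwhm,
            "grid_lo": self.grid_lo,
            "grid_hi": self.grid_hi,
            "grid_step": self.grid_step,
            "coverage": self.coverage,
            "amplitude": self.amplitude,
            "population_threshold": self.population_threshold,
            "seed": self.seed,
            "scale_rules": [
                {"class_label": r.class_label, "lo": r.lo, "hi": r.hi,
                 "factor": r.factor}
                for r in self.scale_rules
            ],
        }
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
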