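# Methods

This note documents the models implemented in `surfvib`, their assumptions,
the numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate.

## Fragment (reduced-Hessian) vibrational analysis

A surface adduct's vibrational problem is restricted to a fragment — the
adsorbed molecule(s) and the surface silanol groups — by **deleting** the
Hessian rows and columns of all other atoms. This is the fixed-environment
convention: non-fragment atoms (silica framework, slab-terminating
hydrogens) have infinite effective mass and do not move. The alternative —
projecting environment coordinates out — would let the environment relax
and is deliberately not used. A consequence is that no translation/rotation
projection is applied either: an embedded fragment has no zero modes, so
all 3N eigenvalues are physical (free-molecule fixtures enter only through
the synthetic generator).

The mass-weighted matrix M^(−1/2)·H·M^(−1/2) is diagonalized with
`numpy.linalg.eigh`; eigenvalues map to wavenumbers as ν̃ = √λ/2πc.
Negative eigenvalues (imaginary modes) are encoded as negative wavenumbers,
kept in the mode list for inspection, and excluded from thermochemistry
with a logged warning — the least surprising of the common conventions.

**Units.** Hessians are kJ mol⁻¹ Å⁻², masses amu, dipole derivatives
D Å⁻¹. IR intensities use
A = N_Aπ/(3c²·4πε₀)·|∂μ/∂Q|², giving 42.256 km mol⁻¹ per (D/Å)² amu⁻¹;
the constant is fixed once in `constants.py` and re-derived from
`scipy.constants` by a dimensional-analysis test.

**Symmetry tolerance.** A Hessian asymmetric beyond 1e-8 (relative to its
largest element) is rejected rather than silently symmetrized.

## Frequency scaling

Harmonic C=O stretch and NH₂ bend frequencies are multiplied by 0.9972 and
1.0102 respectively — the ratios of experimental to calculated frequencies
of the free molecule, absorbing anharmonicity and residual functional error
into one number per mode class. The factors belong to mode *types*; the
implementation assigns the type by a frequency window (C=O: 1600–1800 cm⁻¹,
NH₂ bend: 1500–1600 cm⁻¹, both overridable). Windows must not overlap, as
the class assignment would otherwise be ambiguous. The harmonic reference
values of the free molecule are not available, so the implied unscaled
positions (e.g. 1754/0.9972 ≈ 1758.9 cm⁻¹) are derived quantities, used
only to test the scaling arithmetic.

## Thermochemistry

Adsorbed species get **vibration-only** thermal functions: in the fragment
scheme a bound adsorbate has no meaningful translational or rotational
degrees of freedom, and no PV term. Gas species (the free molecule, its
dimer) get the full RRHO treatment: Sackur–Tetrode translation, classical
rigid rotor with symmetry number (0/1/3 moments of inertia for
atom/linear/nonlinear), harmonic vibrations, and H = U + RT. The identity
G = H − T·S holds by construction and is property-tested. The
vibrational occupation x/(eˣ−1) is evaluated as x·e⁻ˣ/(1−e⁻ˣ) so the
T → 0 limit neither overflows nor loses the U → ZPE, S → 0 behavior.

The counterpoise correction is
ΔE^CP = E_complex − E_A^ghost − E_B^ghost + (E_A^own − E_A^relaxed) +
(E_B^own − E_B^relaxed); fragment deformation terms are included by default
(both conventions exist in practice; a switch disables them). The
variational bound E_ghost ≤ E_own is validated at ledger construction.

Constants are CODATA (R = 8.314462618 J mol⁻¹ K⁻¹), fixed in one table so
that population roundings are reproducible.

The published interaction energies bundled with the package (ΔE^c, ΔE_disp,
ΔH^c, ΔG^c for 5 LC + 7 HC adducts) and the gas-phase dimerization
ΔG = −18 kJ mol⁻¹ are **ingestion data**: reproducing them requires
periodic DFT on undeposited geometries and is out of scope.

## D2 dispersion

E = −Σ_pairs s₆·C₆ᵢⱼ/r⁶·f(r), f(r) = 1/(1+e^(−d(r/R_r−1))), C₆ᵢⱼ =
√(C₆ᵢC₆ⱼ), R_r the sum of elemental van der Waals radii, d = 20. The
default parameters are the published 2006 D2 set for H, C, N, O, Si with
s₆ = 0.75 (PBE), stored in a versioned JSON data file; unit tests use
synthetic parameters so they probe the functional form, not the data file.

2D-periodic slabs are summed in real space over lattice translations within
a cutoff (default 30 Å), visiting a lexicographic half-space of image
vectors so each pair is counted once. The truncation tail scales as
s₆C₆πn/2r_c⁴ (n = areal atom density); at 30 Å it is ~10⁻⁵ relative for
typical slabs, and `lattice_sum_convergence` lets users verify their own
case. The dispersive interaction component is computed by *both* the
subtraction route and the inter-fragment pair sum, asserted equal — a
structural guard rather than a test-only check.

## Populations and spectra

Populations p_i = e^(−ΔG_i/RT)/Σe^(−ΔG_j/RT) are computed after
subtracting min ΔG (shift-stable; populations depend only on ΔΔG).
For comparison with printed tables, rounding is **half-up** to two
decimals — this reproduces borderline entries such as 0.006 → 0.01.
Low- and high-coverage adducts form separate ensembles, and an ensemble
rejects mixed coverage at construction.

Band synthesis places one Gaussian per mode at its scaled frequency with
FWHM 20 cm⁻¹ on a 1500–1800 cm⁻¹ grid at 0.5 cm⁻¹ (experimental resolution
was 2 cm⁻¹). The default amplitude convention is **height** (peak height =
intensity); **area** (integral = intensity) is available, and the
conservation tests use it because total intensity is then exactly linear in
populations. Ensemble members with population below 0.005 may omit their
mode set (nil components); members above it must have one.

Normalization rescales a simulated trace so its maximum inside a window
matches the experimental maximum — it is idempotent and touches only the
amplitude.

### Baseline and peak reading

A straight line through the window endpoints is subtracted. The corrected
trace is Savitzky–Golay smoothed (cubic, window ≈ half the expected band
FWHM); maxima are local maxima with prominence above max(5% of the
corrected range, 6× the point-noise estimate from first differences).
Shoulders are read as prominent minima of the smoothed second derivative
that are not within half a band-width of a detected maximum. Zero crossings
of the second derivative mark inflection points, which bracket a shoulder
rather than locate it, so the curvature minimum is used instead; its
prominence threshold adapts to the curvature noise floor estimated (via
MAD) in the low-absorbance part of the window. A weak shoulder whose
curvature signature falls below that floor is genuinely undetectable at
the given noise level and is not reported — with the synthetic generator's
default noise (0.5% of the band maximum) a component of ~60% relative
amplitude 18 cm⁻¹ from the main band is recovered reliably, while 35% at
15 cm⁻¹ requires a noiseless trace.

## Synthetic data

The generator stands in for the study's undeposited DFT outputs:

- **Fragments**: the mass-weighted Hessian is assembled as L·Λ(ν̃)·Lᵀ with
  a seeded random orthonormal L, so prescribed frequencies are recovered
  exactly up to floating-point error; dipole derivatives are constructed so
  each mode's intensity equals its prescription. Default prescriptions
  place a strong C=O stretch whose *scaled* position falls at
  1688–1714 cm⁻¹ (red-shifted from the 1754 cm⁻¹ gas-phase value, as
  H-bonding to a silanol shifts it), a weaker NH₂ bend near 1600 cm⁻¹, and
  low-frequency framework modes at 150–900 cm⁻¹.
- **Ensembles**: energy ledgers default to the bundled published tables
  (5 LC + 7 HC), so population outputs are the real study's; mode sets are
  seeded per adduct.
- **Pseudo-experimental traces**: ensemble spectrum + linear baseline
  (offset 0.02, slope 2×10⁻⁴ absorbance/cm⁻¹) + Gaussian noise with σ =
  0.5% of the band maximum, comparable to a well-measured FTIR trace.

All randomness flows from one integer seed through a single
`numpy.random.Generator`.

**What passing tests show — and don't.** Closure tests prove that the
analysis inverts the generator: eigen-analysis recovers prescribed
frequencies/intensities to 1e-6, populations reproduce printed columns,
and band maxima of noisy traces are recovered within ±2 cm⁻¹. They do not
validate the underlying DFT energetics, the harmonic approximation for real
H-bonded adsorbates, or scaling transferability under multiple
simultaneous interactions — the known failure mode at high coverage, where
the simulated band falls ~20 cm⁻¹ below experiment.

## Problem sizes

Synthetic fragments use 1–3 atoms (3–9 modes), ensembles 5–12 adducts, and
spectral grids ≤ 4300 points — sizes chosen so every property test runs in
milliseconds while still exercising full matrices, lattice sums and
end-to-end closure.

## Known limitations

- No D3/D4 dispersion, three-body terms or reciprocal-space acceleration.
- No hindered-rotor or quasi-RRHO entropy corrections.
- Lorentzian/Voigt line shapes and population fitting to experiment
  (the inverse problem) are out of scope.
- JCAMP-DX support covers the uncompressed (XY..XY) AFFN variant only.
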