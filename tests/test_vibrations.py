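"""Fragment Hessian analysis: frequencies, intensities, mode scaling."""

import math

import numpy as np
import pytest
import scipy.constants as sc
from hypothesis import given
from hypothesis import strategies as st

from surfvib import constants as K
from surfvib.vibrations import (
    DEFAULT_SCALE_RULES,
    FragmentHessian,
    ModeSet,
    ScaleRule,
    apply_scaling,
    ir_intensities,
    normal_modes,
    reduce_hessian,
)


def random_orthonormal(n, rng):
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    return q


def hessian_from_frequencies(freqs, masses, rng):
    """Independent construction: mass-weighted L·Λ·Lᵀ, un-mass-weighted."""
    lam = np.array([K.wavenumber_to_eigenvalue(f) for f in freqs])
    L = random_orthonormal(len(freqs), rng)
    sqrt_m = np.repeat(np.sqrt(masses), 3)
    H = ((L * lam) @ L.T) * np.outer(sqrt_m, sqrt_m)
    return H, L


class TestReduceHessian:
    def test_full_fragment_is_identity(self, rng):
        H = rng.standard_normal((6, 6))
        H = H + H.T
        fh = reduce_hessian(H, [0, 1], masses=[1.0, 16.0])
        assert np.array_equal(fh.H, H)

    def test_single_atom_block(self, rng):
        H = rng.standard_normal((6, 6))
        H = H + H.T
        fh = reduce_hessian(H, [1], masses=[1.0, 16.0])
        assert fh.H.shape == (3, 3)
        assert np.array_equal(fh.H, H[3:, 3:])
        assert fh.masses == pytest.approx([16.0])

    def test_uncoupled_block_gives_identical_frequencies(self, rng):
        """A fragment with no coupling to its environment vibrates the same
        whether analysed reduced or in the full system."""
        freqs_frag = [500.0, 1000.0, 1500.0, 1600.0, 1700.0, 1754.0]
        masses = np.array([1.0, 12.0])
        Hf, _ = hessian_from_frequencies(freqs_frag, masses, rng)
        env_freqs = [200.0, 300.0, 400.0]
        lam_env = [K.wavenumber_to_eigenvalue(f) for f in env_freqs]
        He = np.diag(lam_env) * 28.0  # one Si environment atom, uncoupled
        full = np.zeros((9, 9))
        full[:6, :6] = Hf
        full[6:, 6:] = He
        all_masses = np.array([1.0, 12.0, 28.0])
        reduced = normal_modes(reduce_hessian(full, [0, 1], all_masses))
        direct = normal_modes(FragmentHessian(H=Hf, masses=masses))
        whole = normal_modes(FragmentHessian(H=full, masses=all_masses))
        np.testing.assert_allclose(reduced.frequencies, direct.frequencies,
                                   rtol=1e-9)
        # fragment frequencies are a subset of the full-system ones
        for f in reduced.frequencies:
            assert np.min(np.abs(whole.frequencies - f)) < 1e-6 * max(f, 1.0)

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            reduce_hessian(np.zeros((6, 6)), [], masses=[1.0, 1.0])

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            reduce_hessian(np.zeros((6, 6)), [0, 0], masses=[1.0, 1.0])


class TestNormalModes:
    def test_diatomic_stretch_closed_form(self):
        """Two unit masses coupled by k along x: ν̃ = √(2k/m)/(2πc)."""
        k = 500.0  # kJ mol⁻¹ Å⁻²
        H = np.zeros((6, 6))
        H[0, 0] = H[3, 3] = k
        H[0, 3] = H[3, 0] = -k
        ms = normal_modes(FragmentHessian(H=H, masses=[1.0, 1.0]))
        lam_si = 2 * k * 1000.0 / (sc.N_A * sc.atomic_mass * 1e-20)
        expected = math.sqrt(lam_si) / (2 * math.pi * sc.c * 100.0)
        assert ms.frequencies[-1] == pytest.approx(expected, rel=1e-10)
        assert np.abs(ms.frequencies[:-1]).max() < 1e-6

    def test_prescribed_frequencies_recovered(self, rng):
        freqs = [500.0, 1000.0, 1500.0]
        H, _ = hessian_from_frequencies(freqs, [1.0], rng)
        ms = normal_modes(FragmentHessian(H=H, masses=[1.0]))
        np.testing.assert_allclose(ms.frequencies, freqs, rtol=1e-6)

    def test_zero_matrix_all_zero(self):
        ms = normal_modes(FragmentHessian(H=np.zeros((3, 3)), masses=[1.0]))
        assert np.all(ms.frequencies == 0.0)

    def test_imaginary_mode_reported_negative(self, rng):
        lam = [K.wavenumber_to_eigenvalue(f) for f in (-300.0, 800.0, 1200.0)]
        L = random_orthonormal(3, rng)
        H = (L * lam) @ L.T
        ms = normal_modes(FragmentHessian(H=H, masses=[1.0]))
        assert ms.frequencies[0] == pytest.approx(-300.0, rel=1e-8)

    def test_asymmetric_hessian_rejected(self):
        H = np.zeros((3, 3))
        H[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            FragmentHessian(H=H, masses=[1.0])

    def test_orthonormality_and_reconstruction(self, rng):
        freqs = np.linspace(200, 1800, 9)
        H, _ = hessian_from_frequencies(freqs, [1.0, 12.0, 16.0], rng)
        fh = FragmentHessian(H=H, masses=[1.0, 12.0, 16.0])
        ms = normal_modes(fh)
        gram = ms.modes.T @ ms.modes
        assert np.abs(gram - np.eye(9)).max() < 1e-8
        mw = fh.mass_weighted()
        lam = np.array([K.wavenumber_to_eigenvalue(f) for f in ms.frequencies])
        recon = (ms.modes * lam) @ ms.modes.T
        assert np.abs(recon - mw).max() <= 1e-8 * np.abs(mw).max()

    @given(seed=st.integers(0, 1000))
    def test_permutation_invariance(self, seed):
        """Frequencies do not depend on atom ordering."""
        rng = np.random.default_rng(seed)
        masses = np.array([1.0, 12.0, 16.0])
        freqs = np.sort(rng.uniform(100, 2000, 9))
        H, _ = hessian_from_frequencies(freqs, masses, rng)
        perm = rng.permutation(3)
        rows = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in perm])
        Hp = H[np.ix_(rows, rows)]
        a = normal_modes(FragmentHessian(H=H, masses=masses))
        b = normal_modes(FragmentHessian(H=Hp, masses=masses[perm]))
        np.testing.assert_allclose(a.frequencies, b.frequencies,
                                   rtol=1e-8, atol=1e-6)


class TestIRIntensities:
    def _modeset(self, H, masses):
        fh = FragmentHessian(H=H, masses=masses)
        return fh, normal_modes(fh)

    def test_zero_dipole_derivatives_zero_intensity(self, rng):
        H, _ = hessian_from_frequencies([500.0, 1000.0, 1500.0], [1.0], rng)
        fh = FragmentHessian(H=H, masses=[1.0],
                             dipole_derivatives=np.zeros((3, 3)))
        ms = ir_intensities(fh, normal_modes(fh))
        assert np.all(ms.intensities == 0.0)

    def test_mode_aligned_with_dipole_direction(self):
        """Only the mode along the dipole-derivative direction absorbs."""
        lam = [K.wavenumber_to_eigenvalue(f) for f in (500.0, 1000.0, 1500.0)]
        H = np.diag(lam)  # modes are the Cartesian axes
        dd = np.zeros((3, 3))
        dd[0, 0] = 1.0  # ∂μx/∂x1 only
        fh = FragmentHessian(H=H, masses=[1.0], dipole_derivatives=dd)
        ms = ir_intensities(fh, normal_modes(fh))
        active = np.nonzero(ms.intensities > 1e-12)[0]
        assert list(active) == [0]
        assert ms.intensities[0] == pytest.approx(K.IR_INT_KM_PER_MOL)

    def test_doubling_derivatives_quadruples_intensities(self, rng):
        H, _ = hessian_from_frequencies(
            np.linspace(300, 1800, 6), [1.0, 16.0], rng)
        dd = rng.standard_normal((6, 3))
        fh1 = FragmentHessian(H=H, masses=[1.0, 16.0], dipole_derivatives=dd)
        fh2 = FragmentHessian(H=H, masses=[1.0, 16.0],
                              dipole_derivatives=2 * dd)
        ms = normal_modes(fh1)
        i1 = ir_intensities(fh1, ms).intensities
        i2 = ir_intensities(fh2, ms).intensities
        np.testing.assert_allclose(i2, 4 * i1, rtol=1e-10)

    def test_missing_derivatives_error_mentions_workflow(self, rng):
        H, _ = hessian_from_frequencies([500.0, 1000.0, 1500.0], [1.0], rng)
        fh = FragmentHessian(H=H, masses=[1.0])
        with pytest.raises(ValueError, match="intensity-free"):
            ir_intensities(fh, normal_modes(fh))

    def test_conversion_constant_dimensional_analysis(self):
        """Recompute the km·mol⁻¹/((D/Å)²·amu⁻¹) constant from first
        principles: A = N_A·π/(3·c²·4πε₀)·|∂μ/∂Q|² in SI, rescaled."""
        debye = 1e-21 / sc.c
        expected = (
            sc.N_A * math.pi / (3 * sc.c**2 * 4 * math.pi * sc.epsilon_0)
            * (debye / 1e-10) ** 2 / sc.atomic_mass / 1000.0
        )
        assert K.IR_INT_KM_PER_MOL == pytest.approx(expected, rel=1e-12)
        assert K.IR_INT_KM_PER_MOL == pytest.approx(42.256, rel=1e-4)


class TestApplyScaling:
    def _ms(self, freqs):
        n = len(freqs)
        return ModeSet(frequencies=np.array(freqs), modes=np.eye(n))

    def test_co_stretch_factor_maps_harmonic_to_observed(self):
        """The harmonic value implied by the gas-phase C=O at 1754 cm⁻¹ and
        factor 0.9972 is 1754/0.9972 = 1758.925 cm⁻¹; scaling recovers it."""
        ms = self._ms([1754.0 / 0.9972])
        scaled = apply_scaling(ms, DEFAULT_SCALE_RULES)
        assert scaled.scaled_frequencies[0] == pytest.approx(1754.0, abs=1e-9)
        assert scaled.scale_class[0] == "CO_stretch"

    def test_nh2_window_uses_its_own_factor(self):
        ms = self._ms([1580.0])
        scaled = apply_scaling(ms, DEFAULT_SCALE_RULES)
        assert scaled.scaled_frequencies[0] == pytest.approx(1580.0 * 1.0102)
        assert scaled.scale_class[0] == "NH2_bend"

    def test_unit_factor_is_identity(self):
        ms = self._ms([1700.0])
        rules = [ScaleRule("CO_stretch", 1600.0, 1800.0, 1.0)]
        scaled = apply_scaling(ms, rules)
        assert scaled.scaled_frequencies[0] == 1700.0

    def test_mode_outside_windows_unchanged(self):
        ms = self._ms([900.0])
        scaled = apply_scaling(ms, DEFAULT_SCALE_RULES)
        assert scaled.scaled_frequencies[0] == 900.0
        assert scaled.scale_class[0] is None

    def test_overlapping_windows_rejected(self):
        rules = [
            ScaleRule("a", 1500.0, 1650.0, 1.0),
            ScaleRule("b", 1600.0, 1800.0, 1.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            apply_scaling(self._ms([1700.0]), rules)

    def test_ordering_preserved_within_class(self, rng):
        freqs = np.sort(rng.uniform(1600, 1800, 5))
        scaled = apply_scaling(self._ms(freqs), DEFAULT_SCALE_RULES)
        assert np.all(np.diff(scaled.scaled_frequencies) >= 0)
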