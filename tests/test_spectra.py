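"""Spectrum calculators: Boltzmann weights, lifetime bands, XAS/RIXS/PFY
closed forms, additivity and interference limits, orientational averaging."""

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.special import voigt_profile

from frexs import (
    GammaModel,
    HEMIN_GAMMA_MODEL,
    FixedPolarization,
    RuleFlags,
    SpectroscopyConfig,
    assemble_hamiltonian,
    boltzmann_weights,
    build_basis,
    diagonalize,
    gamma_of_energy,
    make_dimer_geometry,
    monomer_eigensystem,
    orientational_average,
    pfy,
    rixs,
    xas,
)
from frexs.spectra import LOWEST_KRAMERS_DOUBLET, RixsMap, SpectrumWarning
from conftest import two_level_monomer, three_state_monomer


def cold_config(**kw):
    defaults = dict(
        excitation_grid=np.linspace(700, 740, 400),
        emission_grid=np.linspace(695, 742, 400),
        initial_state_mode=LOWEST_KRAMERS_DOUBLET,
        gamma_model=GammaModel.constant(0.2),
    )
    defaults.update(kw)
    return SpectroscopyConfig(**defaults)


def uncoupled_dimer_eigensystem(m, rotation_deg=0.0):
    geometry = make_dimer_geometry(7.0, rotation_deg)
    b = build_basis(m, m, "TPA")
    return diagonalize(
        assemble_hamiltonian(b, m, m, geometry, RuleFlags.uncoupled())
    )


class TestWeightsAndGamma:
    def test_degenerate_pair_is_half_half(self):
        assert np.allclose(boltzmann_weights([0.0, 0.0], 300.0), [0.5, 0.5])

    def test_room_temperature_closed_form(self):
        w = boltzmann_weights([0.0, 0.1], 300.0)
        ratio = np.exp(-0.1 / 0.025852)  # k_B * 300 K = 0.025852 eV
        assert w[1] / w[0] == pytest.approx(ratio, rel=1e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-15)

    def test_zero_temperature_limit(self):
        assert np.allclose(boltzmann_weights([0.0, 0.1], 0.0), [1.0, 0.0])
        with pytest.raises(ValueError):
            boltzmann_weights([], 300.0)

    @pytest.mark.parametrize(
        "energy, expected",
        [(708.0, 0.09), (709.2, 0.26), (710.0, 0.26), (715.0, 0.43), (725.0, 0.61)],
    )
    def test_lifetime_bands(self, energy, expected):
        assert gamma_of_energy(energy, HEMIN_GAMMA_MODEL) == expected

    def test_single_band_model(self):
        model = GammaModel.constant(0.3)
        assert gamma_of_energy(1e6, model) == 0.3
        with pytest.raises(ValueError):
            GammaModel([710.0, 709.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            GammaModel([710.0], [0.1, -0.2])


class TestXas:
    def test_single_transition_stick(self):
        """One transition at 710 eV with |d|^2 = 3 gives a Voigt line of
        integrated weight 710 * 1 (the E_f - E_i prefactor times |d|^2/3)."""
        m = two_level_monomer(710.0, dipole=(1.0, 1.0, 1.0))
        eig = monomer_eigensystem(m)
        config = cold_config()
        s = xas(eig, config)
        gam = 0.2
        expected = 710.0 * voigt_profile(
            config.excitation_grid - 710.0, config.pulse_sigma, gam
        )
        assert np.allclose(s.intensities, expected, rtol=1e-12)

    def test_zero_dipoles_zero_spectrum(self):
        eig = monomer_eigensystem(two_level_monomer(dipole=(0, 0, 0)))
        s = xas(eig, cold_config())
        assert np.all(s.intensities == 0)

    def test_global_shift_moves_axis(self):
        m = two_level_monomer(712.0)
        s0 = xas(monomer_eigensystem(m), cold_config())
        s1 = xas(monomer_eigensystem(m), cold_config(global_shift=-2.8))
        k0 = np.argmax(s0.intensities)
        k1 = np.argmax(s1.intensities)
        shift = s1.energies[k1] - s0.energies[k0]
        assert shift == pytest.approx(-2.8, abs=0.2)

    def test_uncoupled_dimer_is_twice_the_monomer(self):
        m = three_state_monomer(seed=21)
        config = cold_config()
        mono = xas(monomer_eigensystem(m), config)
        dim = xas(uncoupled_dimer_eigensystem(m), config)
        scale = mono.intensities.max()
        assert np.allclose(dim.intensities, 2 * mono.intensities,
                           rtol=0, atol=1e-10 * scale)

    def test_boltzmann_mode_weights_split_ground(self):
        # split ground doublet (4 meV) + one core state
        from frexs import MonomerStateSet

        d = np.zeros((3, 3, 3), dtype=complex)
        d[0, 2] = d[1, 2] = (0.1, 0, 0)
        d[2, 0] = d[2, 1] = np.conj(d[0, 2])
        ms = MonomerStateSet(
            energies=[0.0, 0.004, 710.0],
            spin_multiplicity=["mixed"] * 3,
            manifold=["ground", "ground", "core"],
            dipoles=d,
        ).validate()
        eig = monomer_eigensystem(ms)
        # wide grid: the Lorentzian tails carry ~0.1% weight per 100 eV
        config = cold_config(initial_state_mode="boltzmann-all-ground",
                             temperature=300.0,
                             excitation_grid=np.linspace(560, 860, 3000))
        s = xas(eig, config)
        # both initial states contribute with Boltzmann weights; the stick
        # positions differ by the 4 meV splitting only, so total integrated
        # intensity matches the weighted sum of both channels
        w = boltzmann_weights([0.0, 0.004], 300.0)
        integral = np.trapezoid(s.intensities, s.energies)
        expected = (w[0] * 710.0 + w[1] * (710.0 - 0.004)) * 0.01 / 3
        assert integral == pytest.approx(expected, rel=5e-3)


class TestRixs:
    def test_single_channel_lorentzian_profile(self):
        """g -> c -> g with one intermediate: peak height follows
        |d|^4 / ((E_exc - E_c)^2 + Gamma^2), maximal on resonance."""
        d, ec, gam = 0.3, 710.0, 0.2
        m = two_level_monomer(ec, dipole=(d, 0.0, 0.0))
        eig = monomer_eigensystem(m)
        config = cold_config(
            polarization_geometry=FixedPolarization(e1=(1, 0, 0), e2=(1, 0, 0)),
            emission_grid=np.linspace(695, 742, 2000),
        )
        detunings = np.array([-1.0, -0.3, 0.0, 0.4, 1.5])
        heights = []
        for det in detunings:
            rm = rixs(eig, config, [ec + det])
            # integrate out the (identical, unit-area) emission Gaussian
            heights.append(np.trapezoid(rm.intensities[0], rm.emission_energies))
        heights = np.asarray(heights)
        expected = d**4 / (detunings**2 + gam**2)
        expected *= heights[2] / expected[2]  # common prefactor
        assert np.allclose(heights, expected, rtol=1e-6)
        assert heights.argmax() == 2

    def test_two_opposed_intermediates_interfere(self):
        """Equal dipoles at detunings +/- Delta: the real parts of the two
        amplitude terms cancel and only the imaginary parts survive."""
        delta, gam, d = 0.5, 0.13, 0.2
        from frexs import MonomerStateSet

        dm = np.zeros((3, 3, 3), dtype=complex)
        dm[0, 1] = dm[0, 2] = (d, 0, 0)
        dm[1, 0] = dm[2, 0] = np.conj(dm[0, 1])
        m = MonomerStateSet(
            energies=[0.0, 710.0 - delta, 710.0 + delta],
            spin_multiplicity=["mixed"] * 3,
            manifold=["ground", "core", "core"],
            dipoles=dm,
        ).validate()
        eig = monomer_eigensystem(m)
        from frexs import rixs_amplitude_tensor

        config = cold_config(gamma_model=GammaModel.constant(gam))
        A = rixs_amplitude_tensor(eig, 0, 710.0, config)
        amp = A[0, 0, 0]  # elastic, xx component
        terms = [d * d / (delta - 1j * gam), d * d / (-delta - 1j * gam)]
        assert amp == pytest.approx(sum(terms), rel=1e-12)
        assert abs(amp.real) < 1e-15
        assert amp.imag == pytest.approx(2 * gam * d * d / (delta**2 + gam**2),
                                         rel=1e-12)

    def test_uncoupled_dimer_adds_when_channels_decouple(self):
        """Monomer dipoles along x, partner rotated 90 deg (dipoles along y):
        the isotropic average separates the two monomers' tensor components,
        so the uncoupled dimer map equals twice the monomer map, elastic
        channel included."""
        m = three_state_monomer(seed=33)
        m.dipoles[..., 1] = 0.0
        m.dipoles[..., 2] = 0.0  # all transitions along x
        m.validate()
        config = cold_config(emission_grid=np.linspace(695, 742, 300))
        exc = [709.5, 710.5]
        mono = rixs(monomer_eigensystem(m), config, exc)
        dim = rixs(uncoupled_dimer_eigensystem(m, rotation_deg=90.0), config, exc)
        scale = mono.intensities.max()
        assert np.allclose(dim.intensities, 2 * mono.intensities,
                           rtol=0, atol=1e-10 * scale)

    def test_uncoupled_dimer_inelastic_channels_add(self):
        """For general dipoles the inelastic final-state intensities of an
        uncoupled dimer equal the summed monomer ones; only the strictly
        elastic channel is coherent across monomers."""
        from frexs import rixs_amplitude_tensor

        m = three_state_monomer(seed=34)
        config = cold_config()
        eig_m = monomer_eigensystem(m)
        eig_d = uncoupled_dimer_eigensystem(m)
        e_exc = 710.2
        A_m = rixs_amplitude_tensor(eig_m, 0, e_exc, config)
        I_m = np.sum(np.abs(A_m) ** 2, axis=(1, 2)) / 9
        A_d = rixs_amplitude_tensor(eig_d, 0, e_exc, config)
        I_d = np.sum(np.abs(A_d) ** 2, axis=(1, 2)) / 9
        # map dimer final configs |a1 b2> back to single-monomer excitations
        pairs = eig_d.vectors  # identity here (diagonal H)
        assert np.allclose(pairs, np.eye(pairs.shape[0]))
        # inelastic finals: exactly one monomer ends excited
        by_energy = {}
        for f, e in enumerate(eig_m.energies):
            if f != 0:
                by_energy[round(e, 9)] = I_m[f]
        matched = 0
        for f, e in enumerate(eig_d.energies):
            key = round(e, 9)
            if key in by_energy and I_d[f] > 0:
                assert I_d[f] == pytest.approx(by_energy[key], rel=1e-10)
                matched += 1
        assert matched >= 2

    def test_empty_intermediate_window_warns_and_zeroes(self):
        eig = monomer_eigensystem(two_level_monomer())
        config = cold_config()
        with pytest.warns(SpectrumWarning):
            rm = rixs(eig, config, [710.0], intermediate_window=(500.0, 1.0))
        assert np.all(rm.intensities == 0)
        assert rm.warning is not None

    def test_gamma_squared_suppression_on_resonance(self):
        """On resonance the single-intermediate denominator is -i Gamma, so
        the peak intensity scales exactly as Gamma^-2."""
        m = two_level_monomer(710.0, dipole=(0.2, 0.0, 0.0))
        eig = monomer_eigensystem(m)
        heights = []
        for gam in (0.5, 1.0):
            config = cold_config(gamma_model=GammaModel.constant(gam))
            rm = rixs(eig, config, [710.0])
            heights.append(rm.intensities.max())
        assert heights[0] / heights[1] == pytest.approx(4.0, rel=1e-12)

    def test_final_state_dipole_ratio_kappa_squared(self):
        """Two final states reached from the same intermediate with dipoles
        differing by kappa produce intensities in ratio kappa^2 squared-"""
        kappa = 3.0
        from frexs import MonomerStateSet, rixs_amplitude_tensor

        d0 = 0.1
        dm = np.zeros((3, 3, 3), dtype=complex)
        dm[0, 2] = (d0, 0, 0)        # g -> c
        dm[1, 2] = (kappa * d0, 0, 0)  # v -> c (kappa-fold stronger emission)
        dm[2, 0] = np.conj(dm[0, 2])
        dm[2, 1] = np.conj(dm[1, 2])
        m = MonomerStateSet(
            energies=[0.0, 2.0, 710.0],
            spin_multiplicity=["mixed"] * 3,
            manifold=["ground", "valence", "core"],
            dipoles=dm,
        ).validate()
        eig = monomer_eigensystem(m)
        config = cold_config()
        A = rixs_amplitude_tensor(eig, 0, 710.0, config)
        I = np.sum(np.abs(A) ** 2, axis=(1, 2)) / 9
        assert I[1] / I[0] == pytest.approx(kappa**2, rel=1e-12)


class TestPfy:
    def test_normalized_gaussian_integrates_to_one(self):
        em = np.linspace(-8, 8, 801)
        gauss = np.exp(-(em**2) / 2) / np.sqrt(2 * np.pi)
        rm = RixsMap(np.array([0.0, 1.0]), em, np.vstack([gauss, gauss]))
        out = pfy(rm, -8, 8)
        assert np.allclose(out.intensities, 1.0, atol=1e-6)
        off = pfy(rm, 6, 8)
        assert np.all(off.intensities < 1e-8)

    def test_matches_independent_quadrature(self):
        m = three_state_monomer(seed=55)
        config = cold_config(emission_grid=np.linspace(695, 742, 1200))
        rm = rixs(monomer_eigensystem(m), config, [710.0, 711.0])
        ours = pfy(rm, 695.0, 735.0)
        em = rm.emission_energies
        mask = (em >= 695.0) & (em <= 735.0)
        # independent trapezoid written out as an explicit loop
        x, y = em[mask], rm.intensities[:, mask]
        ref = np.zeros(y.shape[0])
        for k in range(x.size - 1):
            ref += 0.5 * (x[k + 1] - x[k]) * (y[:, k] + y[:, k + 1])
        assert np.allclose(ours.intensities, ref, rtol=1e-8)
        # and a higher-order rule agrees to its own discretization error
        ref_simpson = simpson(y, x=x, axis=1)
        assert np.allclose(ours.intensities, ref_simpson, rtol=2e-3)

    def test_bad_ranges(self):
        rm = RixsMap(np.array([0.0]), np.linspace(0, 1, 11), np.ones((1, 11)))
        with pytest.raises(ValueError):
            pfy(rm, 5.0, 2.0)
        with pytest.raises(ValueError):
            pfy(rm, 10.0, 20.0)


class TestOrientationalAveraging:
    def test_fixed_dipole_averages_to_third(self):
        d = np.array([0.3, -0.1, 0.7])
        e = np.array([0.0, 0.0, 1.0])
        avg = orientational_average(lambda R: (e @ (R @ d)) ** 2, order=4)
        assert avg == pytest.approx(d @ d / 3, rel=1e-10)

    def test_isotropic_invariant_is_exact(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        frob = np.sum(np.abs(A) ** 2)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.3, -1.2, 0.5]).as_matrix()
        assert np.sum(np.abs(R @ A @ R.T) ** 2) == pytest.approx(frob, rel=1e-12)

    def test_rigid_rotation_leaves_averaged_spectra_unchanged(self):
        """Rotating the entire dimer (geometry and both monomers) must not
        change orientation-averaged XAS or perpendicular-detection RIXS."""
        from scipy.spatial.transform import Rotation

        m = three_state_monomer(seed=77)
        R0 = Rotation.from_rotvec([0.4, 1.1, -0.8]).as_matrix()
        m_rot = three_state_monomer(seed=77)
        m_rot.orientation = R0 @ m_rot.orientation

        config = cold_config(
            polarization_geometry="perpendicular-detection",
            quadrature_order=10,
            emission_grid=np.linspace(695, 742, 200),
        )
        exc = [710.3]

        def dimer_map(monomer, sep):
            from frexs import DimerGeometry

            geometry = DimerGeometry(sep, 0.0)
            b = build_basis(monomer, monomer, "TPA")
            eig = diagonalize(assemble_hamiltonian(b, monomer, monomer, geometry))
            return rixs(eig, config, exc), xas(eig, config)

        rm0, x0 = dimer_map(m, np.array([0.0, 0.0, 7.0]))
        rm1, x1 = dimer_map(m_rot, R0 @ np.array([0.0, 0.0, 7.0]))
        scale = rm0.intensities.max()
        assert np.allclose(rm1.intensities, rm0.intensities,
                           rtol=0, atol=1e-8 * scale)
        assert np.allclose(x1.intensities, x0.intensities,
                           rtol=0, atol=1e-8 * x0.intensities.max())

    def test_convergence_machinery(self):
        calls = []

        def evaluator(R):
            calls.append(1)
            return 1.0  # constant: converges immediately

        assert orientational_average(evaluator, order=2) == pytest.approx(1.0)
        with pytest.raises(RuntimeError):
            # impossible tolerance with a tiny cap triggers the diagnostic
            rng = np.random.default_rng(0)
            M = rng.normal(size=(3, 3))
            orientational_average(
                lambda R: float((R @ M).sum() ** 4), order=2, tol=1e-30, max_order=4
            )

    def test_all_outputs_non_negative(self):
        m = three_state_monomer(seed=91)
        config = cold_config(emission_grid=np.linspace(695, 742, 150))
        eig = monomer_eigensystem(m)
        assert np.all(xas(eig, config).intensities >= 0)
        rm = rixs(eig, config, [709.0, 711.0])
        assert np.all(rm.intensities >= 0)
        assert np.all(pfy(rm, 695, 741).intensities >= 0)
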