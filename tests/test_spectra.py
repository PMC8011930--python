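"""Oscillator strengths and spectrum construction."""

import warnings

import numpy as np
import pytest

from ccxas import fci
from ccxas.basis import BasisAssignment
from ccxas.ccsd import solve_amplitudes
from ccxas.constants import HARTREE_TO_EV
from ccxas.eom import (JacobianOperator, biorthonormalize, davidson_solve,
                       solve_multipliers)
from ccxas.molecule import load_geometry
from ccxas.scf import compute_reference
from ccxas.spectra import (broaden, read_spectrum, spectrum_from_records,
                           transition_strengths, write_spectrum, _OneBodyBar)

from conftest import Reference


def _eom_spectrum(ref, n_roots, res_tol=1e-7, e_tol=1e-9):
    H = ref.so_hamiltonian()
    state = solve_amplitudes(H, conv_tol=1e-10)
    op = JacobianOperator(H, state.t1, state.t2)
    R = davidson_solve(op, n_roots, "right", res_tol=res_tol, e_tol=e_tol)
    L = davidson_solve(op, n_roots, "left", res_tol=res_tol, e_tol=e_tol)
    lam = solve_multipliers(op, conv_tol=1e-10)
    states = biorthonormalize(L, R, lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recs = transition_strengths(states, lam, H, state.t1, state.t2)
    return H, state, lam, states, recs


class TestOscillatorStrengthsFCILimit:
    def test_h2_strengths_equal_fci(self, h2_631g):
        """Two electrons: EOM-CCSD is exact, so energies and length-gauge
        oscillator strengths must equal FCI's."""
        ref = h2_631g
        n = ref.scf.n_mo
        _, _, _, states, recs = _eom_spectrum(ref, 6)
        h_so, g_anti = fci.spin_orbital_integrals(ref.h_mo, ref.g_mo)
        om_f, f_f = fci.fci_oscillator_strengths(
            h_so, g_anti, ref.so_dipoles(), 2, 2 * n, n_states=6
        )
        np.testing.assert_allclose(
            [s.omega for s in states], om_f, atol=1e-8
        )
        np.testing.assert_allclose([r.f for r in recs], f_f, atol=1e-6)

    def test_ground_state_dipole_equals_fci(self, h2_631g):
        """<L0|mubar|R0> against the FCI ground-state expectation value."""
        ref = h2_631g
        H = ref.so_hamiltonian()
        state = solve_amplitudes(H, conv_tol=1e-11)
        op = JacobianOperator(H, state.t1, state.t2)
        lam = solve_multipliers(op, conv_tol=1e-11)
        h_so, g_anti = fci.spin_orbital_integrals(ref.h_mo, ref.g_mo)
        w, V, dets = fci.fci_states(h_so, g_anti, 2, 2 * ref.scf.n_mo)
        for a in range(3):
            bar = _OneBodyBar(H, H.dip_blocks[a], state.t1, state.t2)
            mu_cc = bar.ground_expectation(lam)
            M = fci.build_one_body(dets, ref.so_dipoles()[a])
            mu_fci = V[:, 0] @ M @ V[:, 0]
            assert mu_cc == pytest.approx(mu_fci, abs=1e-7)

    def test_forbidden_transitions_are_dark(self, h2_631g):
        # homonuclear molecule: gerade <- gerade transitions carry f = 0
        _, _, _, states, recs = _eom_spectrum(h2_631g, 6)
        fs = np.array([r.f for r in recs])
        assert np.sum(np.abs(fs) > 1e-10) >= 1  # some bright state exists
        assert np.min(np.abs(fs)) < 1e-10       # and some dark ones

    def test_rotation_invariance(self):
        """f is a scalar contraction over Cartesian components: rotating the
        molecular frame must not change it."""
        xyz1 = "2\nh2\nH 0 0 0\nH 0 0 0.74\n"
        c, s = np.cos(0.7), np.sin(0.7)
        z2 = np.array([0.0, 0.74 * s, 0.74 * c])
        xyz2 = f"2\nh2 rotated\nH 0 0 0\nH 0 {z2[1]:.10f} {z2[2]:.10f}\n"
        r1 = Reference(load_geometry(xyz1), BasisAssignment("6-31g"))
        r2 = Reference(load_geometry(xyz2), BasisAssignment("6-31g"))
        _, _, _, _, recs1 = _eom_spectrum(r1, 4)
        _, _, _, _, recs2 = _eom_spectrum(r2, 4)
        np.testing.assert_allclose(
            sorted(r.f for r in recs1), sorted(r.f for r in recs2), atol=1e-8
        )


class TestBroadening:
    def test_single_stick_peak_height_closed_form(self):
        spec = broaden([(400.0, 0.01)], fwhm_ev=0.3,
                       grid=np.linspace(395, 405, 10001))
        peak = spec.intensity.max()
        assert peak == pytest.approx(2 * 0.01 / (np.pi * 0.3), rel=1e-6)
        assert spec.grid[np.argmax(spec.intensity)] == pytest.approx(400.0, abs=1e-3)

    def test_curve_integral_equals_total_strength(self):
        sticks = [(399.5, 0.01), (401.2, 0.02), (403.0, 0.005)]
        spec = broaden(sticks, fwhm_ev=0.3,
                       grid=np.linspace(250, 550, 200001))
        integral = np.trapezoid(spec.intensity, spec.grid)
        assert integral == pytest.approx(0.035, rel=0.01)

    def test_empty_sticks_zero_curve(self):
        spec = broaden([], fwhm_ev=0.3, grid=np.linspace(0, 10, 11))
        np.testing.assert_array_equal(spec.intensity, 0.0)

    def test_default_fwhm(self):
        spec = broaden([(400.0, 1.0)])
        assert spec.fwhm == 0.3

    @pytest.mark.parametrize("bad", [0.0, -0.3])
    def test_invalid_fwhm(self, bad):
        with pytest.raises(ValueError):
            broaden([(400.0, 1.0)], fwhm_ev=bad)

    def test_non_monotonic_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            broaden([(1.0, 1.0)], grid=np.array([0.0, 2.0, 1.0]))


class TestSpectrumIO:
    def test_round_trip_preserves_sticks_bitwise(self, tmp_path):
        sticks = np.array([[400.123456789012, 0.0123456789],
                           [401.5, 3.2e-4]])
        spec = broaden(sticks, fwhm_ev=0.3)
        path = tmp_path / "spec.csv"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        np.testing.assert_array_equal(back.sticks, sticks)
        np.testing.assert_array_equal(back.grid, spec.grid)
        np.testing.assert_array_equal(back.intensity, spec.intensity)
        assert back.fwhm == 0.3

    def test_shift_column_optional(self, tmp_path):
        spec = broaden([(400.0, 0.01)], fwhm_ev=0.3)
        p1 = tmp_path / "plain.csv"
        p2 = tmp_path / "shifted.csv"
        write_spectrum(spec, p1)
        write_spectrum(spec, p2, shift_ev=-0.5)
        assert "energy_shifted_eV" not in p1.read_text()
        assert "energy_shifted_eV" in p2.read_text()


class TestMultilevelStrengthLimits:
    def test_full_active_methods_reproduce_ccsd_strengths(self, water_sto3g):
        """With every orbital active, MLCCSD and CCSD-in-HF oscillator
        strengths equal CCSD's."""
        import warnings

        from ccxas.methods import solve_excited_states, solve_ground_state
        from ccxas.partition import full_active_space

        ref = water_sto3g
        space = full_active_space(ref.scf.C, ref.scf.n_occ, ref.scf.eps)
        fs = {}
        for method, spc in (("ccsd", None), ("mlccsd", space),
                            ("ccsd-in-hf", space)):
            res = solve_ground_state(ref.ints, ref.scf, method, spc,
                                     conv_tol=1e-10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ex = solve_excited_states(res, 4, res_tol=1e-7, e_tol=1e-9)
            fs[method] = np.array([r.f for r in ex.records])
        np.testing.assert_allclose(fs["mlccsd"], fs["ccsd"], atol=1e-8)
        np.testing.assert_allclose(fs["ccsd-in-hf"], fs["ccsd"], atol=1e-8)
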