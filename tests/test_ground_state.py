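"""Ground-state coupled cluster: oracle agreement, limits, invariances.

The two independent oracles are (i) brute-force FCI in the determinant
basis and (ii) the determinant-space similarity transform, which evaluates
<mu|exp(-T) H exp(T)|HF> exactly for arbitrary amplitudes.
"""

import numpy as np
import pytest

from ccxas import fci
from ccxas.ccsd import (ccsd_energy, ccsd_residual, doubles_mask, mp2_guess,
                        solve_amplitudes, spatial_to_so_active)
from ccxas.methods import build_effective_fock, solve_ground_state
from ccxas.moints import SpinOrbitalHamiltonian
from ccxas.partition import frozen_core_space, full_active_space

from conftest import random_amplitude_vector


class TestResidualOracle:
    def test_residual_matches_determinant_space(self, h4_sto3g, rng):
        """Omega from the einsum code equals <mu|Hbar|HF> from the explicit
        determinant-space similarity transform, at random amplitudes."""
        ref = h4_sto3g
        H = ref.so_hamiltonian()
        no, nv = H.nocc, H.nvirt
        t1, t2 = random_amplitude_vector(rng, no, nv, scale=0.05)
        o1, o2 = ccsd_residual(H, t1, t2)
        e = ccsd_energy(H, t1, t2)

        h_so, g_anti = fci.spin_orbital_integrals(ref.h_mo, ref.g_mo)
        ds = fci.DeterminantSpace(2 * ref.scf.n_mo, 4)
        Hdet = fci.build_hamiltonian(ds.dets, h_so, g_anti)
        Hbar = ds.similarity_transform(Hdet, t1, t2)
        M00, eta, xi, _ = ds.amplitude_blocks(Hbar)

        assert M00 == pytest.approx(e + ref.scf.e_hf - ref.ints.e_nuc, abs=1e-12)
        ns = len(ds.singles)
        np.testing.assert_allclose(o1, xi[:ns].reshape(no, nv), atol=1e-12)
        for k, (i, j, a, b) in enumerate(ds.doubles):
            assert o2[i, j, a, b] == pytest.approx(xi[ns + k], abs=1e-12)

    def test_zero_amplitudes_closed_form(self, water_sto3g):
        """At T = 0 over canonical orbitals the singles residual vanishes
        and the doubles residual is the bare <ij||ab> block."""
        H = water_sto3g.so_hamiltonian()
        t1 = np.zeros((H.nocc, H.nvirt))
        t2 = np.zeros((H.nocc, H.nocc, H.nvirt, H.nvirt))
        o1, o2 = ccsd_residual(H, t1, t2)
        np.testing.assert_allclose(o1, 0.0, atol=1e-10)
        np.testing.assert_allclose(o2, H.oovv, atol=1e-12)


class TestTwoElectronExactness:
    @pytest.mark.parametrize("ref_name", ["h2_sto3g", "h2_631g"])
    def test_ccsd_equals_fci(self, ref_name, request):
        ref = request.getfixturevalue(ref_name)
        H = ref.so_hamiltonian()
        state = solve_amplitudes(H, conv_tol=1e-10)
        h_so, g_anti = fci.spin_orbital_integrals(ref.h_mo, ref.g_mo)
        w, _, _ = fci.fci_states(h_so, g_anti, 2, 2 * ref.scf.n_mo,
                                 e_nuc=ref.ints.e_nuc)
        assert state.e_total == pytest.approx(w[0], abs=1e-9)


class TestConvergedSolutions:
    def test_converged_residual_below_threshold(self, h4_converged):
        _, H, state = h4_converged
        o1, o2 = ccsd_residual(H, state.t1, state.t2)
        from ccxas.ccsd import residual_norm

        assert residual_norm(o1, o2) < 1e-6
        assert state.converged

    def test_mask_violation_raises(self, h4_converged):
        _, H, state = h4_converged
        mask = np.zeros_like(state.t2, dtype=bool)
        with pytest.raises(ValueError, match="active-space pattern"):
            ccsd_residual(H, state.t1, state.t2, t2_mask=mask)


class TestLimitEquivalences:
    def test_full_active_mlccsd_and_in_hf_equal_ccsd(self, water_631g):
        ref = water_631g
        r_c = solve_ground_state(ref.ints, ref.scf, "ccsd", conv_tol=1e-9)
        space = full_active_space(ref.scf.C, ref.scf.n_occ, ref.scf.eps)
        r_m = solve_ground_state(ref.ints, ref.scf, "mlccsd", space, conv_tol=1e-9)
        r_r = solve_ground_state(ref.ints, ref.scf, "ccsd-in-hf", space, conv_tol=1e-9)
        assert r_m.state.e_total == pytest.approx(r_c.state.e_total, abs=1e-10)
        assert r_r.state.e_total == pytest.approx(r_c.state.e_total, abs=1e-10)

    def test_empty_active_doubles_reduces_to_ccs(self, water_sto3g):
        """With no active doubles the model is CCS; over a canonical HF
        reference CCS has zero correlation energy (Brillouin)."""
        H = water_sto3g.so_hamiltonian()
        mask = np.zeros((H.nocc, H.nocc, H.nvirt, H.nvirt), bool)
        state = solve_amplitudes(H, t2_mask=mask, conv_tol=1e-9)
        assert state.e_corr == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(state.t2, 0.0)

    def test_mlccsd_energy_between_ccs_and_ccsd(self, water_631g):
        ref = water_631g
        H = ref.so_hamiltonian()
        full = solve_amplitudes(H, conv_tol=1e-8)
        n_occ, n_mo = ref.scf.n_occ, ref.scf.n_mo
        act_occ = spatial_to_so_active([i >= 1 for i in range(n_occ)])
        act_virt = spatial_to_so_active([a < 6 for a in range(n_mo - n_occ)])
        mask = doubles_mask(H.nocc, H.nvirt, act_occ, act_virt)
        ml = solve_amplitudes(H, t2_mask=mask, conv_tol=1e-8)
        assert full.e_corr < ml.e_corr < 0.0

    def test_nesting_monotonicity(self, water_631g):
        """|E_MLCCSD - E_CCSD| is non-increasing along nested active spaces."""
        ref = water_631g
        H = ref.so_hamiltonian()
        full = solve_amplitudes(H, conv_tol=1e-9)
        n_occ, n_virt = ref.scf.n_occ, ref.scf.n_mo - ref.scf.n_occ
        gaps = []
        for n_act_virt in (3, 5, 8, n_virt):
            act_occ = spatial_to_so_active(np.ones(n_occ, bool))
            act_virt = spatial_to_so_active(
                np.arange(n_virt) < n_act_virt
            )
            mask = doubles_mask(H.nocc, H.nvirt, act_occ, act_virt)
            ml = solve_amplitudes(H, t2_mask=mask, conv_tol=1e-9)
            gaps.append(abs(ml.e_corr - full.e_corr))
        for a, b in zip(gaps, gaps[1:]):
            assert b <= a + 1e-9
        assert gaps[-1] == pytest.approx(0.0, abs=1e-9)


class TestRotationInvariance:
    def test_ccsd_energy_invariant_under_occ_virt_rotations(self, water_sto3g, rng):
        from scipy.stats import ortho_group

        ref = water_sto3g
        H = ref.so_hamiltonian()
        e0 = solve_amplitudes(H, conv_tol=1e-10).e_corr
        n_occ, n_mo = ref.scf.n_occ, ref.scf.n_mo
        C = ref.scf.C.copy()
        Uo = ortho_group.rvs(n_occ, random_state=np.random.RandomState(5))
        Uv = ortho_group.rvs(n_mo - n_occ, random_state=np.random.RandomState(6))
        C[:, :n_occ] = C[:, :n_occ] @ Uo
        C[:, n_occ:] = C[:, n_occ:] @ Uv
        from ccxas.moints import mo_transform

        F = C.T @ ref.scf.fock_ao(ref.ints) @ C
        g = mo_transform(ref.ints.g, C)
        H2 = SpinOrbitalHamiltonian.from_spatial(F, g, n_occ, e_ref=ref.scf.e_hf)
        e1 = solve_amplitudes(H2, conv_tol=1e-10, max_iter=200).e_corr
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestEffectiveFock:
    def test_bare_limit(self, water_631g):
        ref = water_631g
        space = full_active_space(ref.scf.C, ref.scf.n_occ, ref.scf.eps)
        eff = build_effective_fock(ref.scf.fock_ao(ref.ints), space)
        assert eff.is_bare
        np.testing.assert_allclose(eff.matrix, ref.F_mo, atol=1e-10)

    def test_hermitian(self, water_631g):
        ref = water_631g
        space = frozen_core_space(ref.scf.C, ref.scf.n_occ, [0])
        eff = build_effective_fock(ref.scf.fock_ao(ref.ints), space)
        assert not eff.is_bare
        np.testing.assert_allclose(eff.matrix, eff.matrix.T, atol=1e-12)

    def test_frozen_core_matches_h_based_construction(self, water_631g):
        """CCSD-in-HF with frozen 1s equals a frozen-core CCSD whose
        effective one-electron operator is built independently from h and
        the core orbital's Coulomb/exchange field."""
        ref = water_631g
        r_fc = solve_ground_state(
            ref.ints, ref.scf, "ccsd-in-hf",
            frozen_core_space(ref.scf.C, ref.scf.n_occ, [0]),
            conv_tol=1e-9,
        )
        # independent construction: h + sum_{i occ} (2J_i - K_i) in the
        # active MO basis, built from h_mo and MO ERIs rather than from the
        # converged AO Fock matrix
        n_occ = ref.scf.n_occ
        f = ref.h_mo + np.einsum("pqii->pq", ref.g_mo[:, :, :n_occ, :n_occ]) * 2 \
            - np.einsum("piiq->pq", ref.g_mo[:, :n_occ, :n_occ, :])
        keep = np.r_[np.arange(1, n_occ), np.arange(n_occ, ref.scf.n_mo)]
        f_act = f[np.ix_(keep, keep)]
        g_act = ref.g_mo[np.ix_(keep, keep, keep, keep)]
        H = SpinOrbitalHamiltonian.from_spatial(
            f_act, g_act, n_occ - 1, e_ref=ref.scf.e_hf
        )
        state = solve_amplitudes(H, conv_tol=1e-9)
        assert r_fc.state.e_total == pytest.approx(state.e_total, abs=1e-8)


class TestMP2Guess:
    def test_mp2_energy_is_negative_and_below_scf(self, water_631g):
        H = water_631g.so_hamiltonian()
        t1, t2 = mp2_guess(H)
        e_mp2 = ccsd_energy(H, t1, t2)
        assert e_mp2 < 0.0
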