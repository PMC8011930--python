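"""Excited-state machinery: Jacobian action, adjoints, CVS, eigensolver,
multipliers, biorthonormalization.

The Jacobian is checked against (i) a polynomial-exact finite-difference
rule (the residual is a quartic polynomial in the amplitudes, so the 5-point
central rule is exact up to roundoff), (ii) the determinant-space
similarity-transform oracle, and (iii) dense diagonalization.
"""

import numpy as np
import pytest

from ccxas import fci
from ccxas.ccsd import ccsd_residual, doubles_mask, solve_amplitudes, \
    spatial_to_so_active
from ccxas.eom import (CVSSpec, JacobianOperator, biorthonormalize, cc_dot,
                       cvs_project, davidson_solve, eta_vector, pack_unique,
                       solve_multipliers)

from conftest import random_amplitude_vector


@pytest.fixture(scope="module")
def h4_operator(h4_converged):
    ref, H, state = h4_converged
    return ref, H, state, JacobianOperator(H, state.t1, state.t2)


@pytest.fixture(scope="module")
def h4_oracle(h4_converged):
    ref, H, state = h4_converged
    h_so, g_anti = fci.spin_orbital_integrals(ref.h_mo, ref.g_mo)
    ds = fci.DeterminantSpace(2 * ref.scf.n_mo, 4)
    Hdet = fci.build_hamiltonian(ds.dets, h_so, g_anti)
    Hbar = ds.similarity_transform(Hdet, state.t1, state.t2)
    return ds, Hbar, ds.amplitude_blocks(Hbar)


class TestJacobianAction:
    def test_apply_is_exact_directional_derivative(self, h4_operator, rng):
        ref, H, state, op = h4_operator
        no, nv = op.shape1
        r = random_amplitude_vector(rng, no, nv)
        h = 0.5  # any O(1) step: the rule is exact for quartic polynomials

        def omega(s):
            return ccsd_residual(H, state.t1 + s * r[0], state.t2 + s * r[1])

        op_, om, o2p, o2m = omega(h), omega(-h), omega(2 * h), omega(-2 * h)
        d1 = (8 * (op_[0] - om[0]) - (o2p[0] - o2m[0])) / (12 * h)
        d2 = (8 * (op_[1] - om[1]) - (o2p[1] - o2m[1])) / (12 * h)
        s1, s2 = op.apply(r)
        np.testing.assert_allclose(s1, d1, atol=1e-12)
        np.testing.assert_allclose(s2, d2, atol=1e-12)

    def test_transpose_is_adjoint(self, h4_operator, rng):
        _, _, _, op = h4_operator
        no, nv = op.shape1
        r = random_amplitude_vector(rng, no, nv)
        w = random_amplitude_vector(rng, no, nv)
        lhs = cc_dot(w, op.apply(r))
        rhs = cc_dot(op.apply_transpose(w), r)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_dense_matrix_matches_determinant_oracle(self, h4_operator, h4_oracle):
        _, _, _, op = h4_operator
        _, _, (M00, eta_o, xi, Mblk) = h4_oracle
        A_oracle = Mblk - M00 * np.eye(Mblk.shape[0])
        A = op.dense_matrix()
        np.testing.assert_allclose(A, A_oracle, atol=1e-9)

    def test_eta_matches_oracle(self, h4_converged, h4_oracle):
        ref, H, state = h4_converged
        ds, _, (M00, eta_o, _, _) = h4_oracle
        eta = eta_vector(H, state.t1, state.t2)
        no, nv = H.nocc, H.nvirt
        singles = [(i, a) for i in range(no) for a in range(nv)]
        np.testing.assert_allclose(
            pack_unique(eta, singles, ds.doubles), eta_o, atol=1e-12
        )

    def test_full_active_mask_is_identity(self, h4_converged, rng):
        ref, H, state = h4_converged
        no, nv = H.nocc, H.nvirt
        mask = np.ones((no, no, nv, nv), bool)
        op_plain = JacobianOperator(H, state.t1, state.t2)
        op_mask = JacobianOperator(H, state.t1, state.t2, t2_mask=mask)
        r = random_amplitude_vector(rng, no, nv)
        for a, b in zip(op_plain.apply(r), op_mask.apply(r)):
            np.testing.assert_allclose(a, b, atol=1e-12)


class TestCVSProjection:
    def test_idempotent_and_boundary(self, rng):
        no, nv = 6, 4
        spec = CVSSpec(np.array([True, True] + [False] * 4))
        v = random_amplitude_vector(rng, no, nv)
        p = cvs_project(v, spec)
        pp = cvs_project(p, spec)
        np.testing.assert_array_equal(p[0], pp[0])
        np.testing.assert_array_equal(p[1], pp[1])
        # a doubles element with exactly one core occupied index survives
        assert p[1][0, 3, 1, 2] == v[1][0, 3, 1, 2]
        # no core index: zeroed; valence singles: zeroed
        assert p[1][2, 3, 1, 2] == 0.0
        assert np.all(p[0][2:] == 0.0)

    def test_valence_only_vector_projects_to_zero(self, rng):
        no, nv = 4, 3
        spec = CVSSpec(np.array([True, True, False, False]))
        r1 = np.zeros((no, nv))
        r1[2:] = 1.0
        r2 = np.zeros((no, no, nv, nv))
        r2[2, 3, 0, 1] = 1.0
        r2[3, 2, 0, 1] = -1.0
        p = cvs_project((r1, r2), spec)
        assert np.all(p[0] == 0.0) and np.all(p[1] == 0.0)


class TestDavidson:
    def test_matches_dense_diagonalization(self, h4_operator):
        _, _, _, op = h4_operator
        A = op.dense_matrix()
        w = np.sort(np.linalg.eigvals(A).real)
        states = davidson_solve(op, 4, "right", res_tol=1e-8, e_tol=1e-10)
        np.testing.assert_allclose(
            [s.omega for s in states], w[:4], atol=1e-8
        )

    def test_left_right_same_spectrum(self, h4_operator):
        _, _, _, op = h4_operator
        R = davidson_solve(op, 4, "right", res_tol=1e-7, e_tol=1e-9)
        L = davidson_solve(op, 4, "left", res_tol=1e-7, e_tol=1e-9)
        np.testing.assert_allclose(
            [s.omega for s in R], [s.omega for s in L], atol=1e-8
        )

    def test_eigen_relation(self, h4_operator):
        _, _, _, op = h4_operator
        st = davidson_solve(op, 2, "right", res_tol=1e-8, e_tol=1e-10)[0]
        Ar = op.apply((st.r1, st.r2))
        res = (Ar[0] - st.omega * st.r1, Ar[1] - st.omega * st.r2)
        assert np.sqrt(cc_dot(res, res)) < 1e-7

    def test_cvs_right_left_consistent(self, water_631g):
        """CVS window on the O 1s orbital: left and right eigenvalues agree
        and both match the dense spectrum of the projected block."""
        ref = water_631g
        H = ref.so_hamiltonian()
        state = solve_amplitudes(H, conv_tol=1e-9)
        spec = CVSSpec.from_spatial([i == 0 for i in range(ref.scf.n_occ)])
        op = JacobianOperator(H, state.t1, state.t2, cvs=spec)
        R = davidson_solve(op, 4, "right", res_tol=1e-5, e_tol=1e-7)
        L = davidson_solve(op, 4, "left", res_tol=1e-5, e_tol=1e-7)
        np.testing.assert_allclose(
            [s.omega for s in R], [s.omega for s in L], atol=1e-6
        )
        # all physical O 1s excitations sit near -eps(1s); far above valence
        assert min(s.omega for s in R) > 15.0


class TestMultipliers:
    def test_lambda_solves_dense_system(self, h4_operator, h4_oracle):
        ref, H, state, op = h4_operator
        ds, _, (M00, eta_o, xi, Mblk) = h4_oracle
        A_oracle = Mblk - M00 * np.eye(Mblk.shape[0])
        lam = solve_multipliers(op, conv_tol=1e-10)
        l_dense = np.linalg.solve(A_oracle.T, -eta_o)
        no, nv = H.nocc, H.nvirt
        singles = [(i, a) for i in range(no) for a in range(nv)]
        np.testing.assert_allclose(
            pack_unique((lam.l1, lam.l2), singles, ds.doubles),
            l_dense, atol=1e-8,
        )
        assert lam.residual < 1e-10

    def test_cvs_operator_rejected(self, h4_converged):
        ref, H, state = h4_converged
        spec = CVSSpec.from_spatial([True, False])
        op = JacobianOperator(H, state.t1, state.t2, cvs=spec)
        with pytest.raises(ValueError, match="without CVS"):
            solve_multipliers(op)


class TestBiorthonormalization:
    def test_pairing_and_r0(self, h4_operator):
        _, H, state, op = h4_operator
        n = 5
        R = davidson_solve(op, n, "right", res_tol=1e-8, e_tol=1e-10)
        L = davidson_solve(op, n, "left", res_tol=1e-8, e_tol=1e-10)
        lam = solve_multipliers(op, conv_tol=1e-10)
        states = biorthonormalize(L, R, lam)
        for i, si in enumerate(states):
            for j, sj in enumerate(states):
                ov = cc_dot((si.l1, si.l2), (sj.r1, sj.r2))
                assert ov == pytest.approx(1.0 if i == j else 0.0, abs=1e-7)
        for s in states:
            assert s.r0 == pytest.approx(
                -cc_dot((lam.l1, lam.l2), (s.r1, s.r2)), abs=1e-12
            )

    def test_scaling_preserves_right_eigenvectors(self, h4_operator):
        _, _, _, op = h4_operator
        R = davidson_solve(op, 3, "right", res_tol=1e-8, e_tol=1e-10)
        L = davidson_solve(op, 3, "left", res_tol=1e-8, e_tol=1e-10)
        lam = solve_multipliers(op, conv_tol=1e-9)
        r_before = [(s.r1.copy(), s.r2.copy()) for s in R]
        states = biorthonormalize(L, R, lam)
        for s, rb in zip(states, r_before):
            np.testing.assert_allclose(s.r1, rb[0], atol=1e-14)
            np.testing.assert_allclose(s.r2, rb[1], atol=1e-14)


class TestMLCCSDOperator:
    def test_full_active_equals_ccsd_operator(self, h4_converged, rng):
        ref, H, state = h4_converged
        no, nv = H.nocc, H.nvirt
        mask = doubles_mask(
            no, nv,
            spatial_to_so_active(np.ones(no // 2, bool)),
            spatial_to_so_active(np.ones(nv // 2, bool)),
        )
        op_c = JacobianOperator(H, state.t1, state.t2)
        op_m = JacobianOperator(H, state.t1, state.t2, t2_mask=mask)
        r = random_amplitude_vector(rng, no, nv)
        for a, b in zip(op_c.apply(r), op_m.apply(r)):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_masked_rows_are_zero(self, water_631g, rng):
        ref = water_631g
        H = ref.so_hamiltonian()
        n_occ, n_virt = ref.scf.n_occ, ref.scf.n_mo - ref.scf.n_occ
        act_occ = spatial_to_so_active(np.arange(n_occ) >= 1)
        act_virt = spatial_to_so_active(np.arange(n_virt) < 5)
        mask = doubles_mask(H.nocc, H.nvirt, act_occ, act_virt)
        state = solve_amplitudes(H, t2_mask=mask, conv_tol=1e-8)
        op = JacobianOperator(H, state.t1, state.t2, t2_mask=mask)
        r = random_amplitude_vector(rng, H.nocc, H.nvirt)
        s1, s2 = op.apply(r)
        assert np.all(s2[~mask] == 0.0)
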