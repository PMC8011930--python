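"""Cholesky/PAO orbital partitioning invariants."""

import numpy as np
import pytest

from ccxas.basis import BasisAssignment, build_shells
from ccxas.fixtures import make_fixture
from ccxas.partition import (ActiveAtomSelection, PartitionInconsistencyError,
                             cholesky_partition_occupied,
                             construct_active_paos,
                             construct_inactive_virtuals,
                             lowdin_canonical_orthonormalize,
                             partition_orbital_space, semicanonicalize)
from ccxas.scf import compute_reference


@pytest.fixture(scope="module")
def w2_setup():
    """Methylamine + 2 waters with a mixed basis; active = methylamine."""
    fx = make_fixture("methylamine_w2")
    mol = fx.molecule
    ba = BasisAssignment(**fx.suggested_basis)
    ints, scf = compute_reference(mol, ba)
    shells = build_shells(mol, ba)
    return fx, mol, ba, ints, scf, shells


def _partition(setup, atoms, **kw):
    fx, mol, ba, ints, scf, shells = setup
    sel = ActiveAtomSelection.from_atoms(shells, atoms)
    return partition_orbital_space(
        scf.density(), ints.S, scf.fock_ao(ints), scf.n_mo, sel, **kw
    )


class TestOccupiedCholesky:
    def test_all_atoms_active_fills_occupied(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        sel = ActiveAtomSelection.from_atoms(shells, range(mol.n_atoms))
        C_act, C_inact, _ = cholesky_partition_occupied(
            scf.density(), ints.S, sel, threshold=1e-2
        )
        assert C_act.shape[1] == scf.n_occ
        assert C_inact.shape[1] == 0

    def test_density_reconstruction(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        sel = ActiveAtomSelection.from_atoms(shells, fx.suggested_active_atoms)
        C_act, C_inact, neglected = cholesky_partition_occupied(
            scf.density(), ints.S, sel, threshold=1e-2
        )
        C = np.hstack([C_act, C_inact])
        D = scf.density()
        assert np.abs(C @ C.T - D).max() < 1e-8
        assert C_act.shape[1] + C_inact.shape[1] == scf.n_occ
        assert 0.0 <= neglected < 1e-2

    def test_counts_deterministic(self, w2_setup):
        r1 = _partition(w2_setup, (0, 1, 2, 3, 4, 5, 6))[1]
        r2 = _partition(w2_setup, (0, 1, 2, 3, 4, 5, 6))[1]
        assert r1.as_dict() == r2.as_dict()

    def test_loose_threshold_raises(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        sel = ActiveAtomSelection.from_atoms(shells, fx.suggested_active_atoms)
        with pytest.raises(PartitionInconsistencyError):
            # an absurd threshold leaves occupied weight unassigned
            cholesky_partition_occupied(
                scf.density(), ints.S, sel, threshold=1e-2, rank_tol=0.5
            )


class TestPAOs:
    def test_paos_orthogonal_to_occupied(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        sel = ActiveAtomSelection.from_atoms(shells, fx.suggested_active_atoms)
        pao = construct_active_paos(scf.C_occ, ints.S, sel)
        assert pao.shape[1] == len(sel.ao_indices)
        ov = scf.C_occ.T @ ints.S @ pao
        assert np.abs(ov).max() < 1e-10

    def test_all_atoms_span_full_virtual_space(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        sel = ActiveAtomSelection.from_atoms(shells, range(mol.n_atoms))
        pao = construct_active_paos(scf.C_occ, ints.S, sel)
        ortho = lowdin_canonical_orthonormalize(pao, ints.S, 1e-6)
        assert ortho.shape[1] == scf.n_mo - scf.n_occ

    def test_empty_selection_rejected(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        with pytest.raises(ValueError, match="non-empty"):
            ActiveAtomSelection.from_atoms(shells, [])


class TestLowdin:
    def test_orthonormal_output(self, w2_setup, rng):
        fx, mol, ba, ints, scf, shells = w2_setup
        C_raw = rng.standard_normal((ints.n_ao, 8))
        O = lowdin_canonical_orthonormalize(C_raw, ints.S, 1e-6)
        np.testing.assert_allclose(O.T @ ints.S @ O, np.eye(O.shape[1]),
                                   atol=1e-10)

    def test_duplicate_column_drops_rank_by_one(self, w2_setup, rng):
        fx, mol, ba, ints, scf, shells = w2_setup
        C_raw = rng.standard_normal((ints.n_ao, 6))
        C_dup = np.hstack([C_raw, C_raw[:, :1]])
        O = lowdin_canonical_orthonormalize(C_dup, ints.S, 1e-8)
        assert O.shape[1] == 6

    def test_all_dependent_warns_empty(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        C_raw = np.zeros((ints.n_ao, 3))
        with pytest.warns(UserWarning, match="below tolerance"):
            O = lowdin_canonical_orthonormalize(C_raw, ints.S, 1e-8)
        assert O.shape[1] == 0


class TestFullPartition:
    def test_completeness_and_orthonormality(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        space, rep = _partition(w2_setup, fx.suggested_active_atoms)
        Q = space.C_full
        assert space.n_mo == scf.n_mo
        np.testing.assert_allclose(
            Q.T @ ints.S @ Q, np.eye(scf.n_mo), atol=1e-8
        )

    def test_occ_virt_orthogonality(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        space, _ = _partition(w2_setup, fx.suggested_active_atoms)
        C_occ = np.hstack([space.C_occ_act, space.C_occ_inact])
        C_virt = np.hstack([space.C_virt_act, space.C_virt_inact])
        assert np.abs(C_occ.T @ ints.S @ C_virt).max() < 1e-10

    def test_monotonic_counts_under_nesting(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        selections = [(1,), (0, 1), (0, 1, 2, 3, 4, 5, 6),
                      tuple(range(mol.n_atoms))]
        prev_occ = prev_virt = 0
        for atoms in selections:
            space, _ = _partition(w2_setup, atoms)
            assert space.n_occ_act >= prev_occ
            assert space.n_virt_act >= prev_virt
            prev_occ, prev_virt = space.n_occ_act, space.n_virt_act

    def test_semicanonical_blocks_diagonal(self, w2_setup):
        fx, mol, ba, ints, scf, shells = w2_setup
        space, _ = _partition(w2_setup, fx.suggested_active_atoms)
        F = scf.fock_ao(ints)
        for C, eps in [
            (space.C_occ_act, space.eps_occ_act),
            (space.C_occ_inact, space.eps_occ_inact),
            (space.C_virt_act, space.eps_virt_act),
        ]:
            if C.shape[1] == 0:
                continue
            blk = C.T @ F @ C
            np.testing.assert_allclose(blk, np.diag(eps), atol=1e-10)

    def test_semicanonicalization_preserves_blocks(self, w2_setup):
        """Rotations act within blocks only: the spans (projectors) of each
        block are unchanged."""
        fx, mol, ba, ints, scf, shells = w2_setup
        sel = ActiveAtomSelection.from_atoms(shells, fx.suggested_active_atoms)
        from ccxas.partition import (cholesky_partition_occupied,
                                     construct_active_paos,
                                     lowdin_canonical_orthonormalize,
                                     construct_inactive_virtuals, OrbitalSpace)
        D = scf.density()
        C_oa, C_oi, _ = cholesky_partition_occupied(D, ints.S, sel)
        C_occ = np.hstack([C_oa, C_oi])
        C_va = lowdin_canonical_orthonormalize(
            construct_active_paos(C_occ, ints.S, sel), ints.S, 1e-6
        )
        C_vi = construct_inactive_virtuals(C_occ, C_va, ints.S, scf.n_mo, 1e-6)
        raw = OrbitalSpace(C_oa, C_oi, C_va, C_vi)
        rot = semicanonicalize(scf.fock_ao(ints), raw)
        for a, b in [(raw.C_occ_act, rot.C_occ_act),
                     (raw.C_virt_act, rot.C_virt_act)]:
            np.testing.assert_allclose(a @ a.T, b @ b.T, atol=1e-8)

    def test_canonical_limit_recovers_orbital_energies(self, water_631g):
        from ccxas.partition import full_active_space

        ref = water_631g
        space = full_active_space(ref.scf.C, ref.scf.n_occ)
        rot = semicanonicalize(ref.scf.fock_ao(ref.ints), space)
        np.testing.assert_allclose(
            np.r_[rot.eps_occ_act, rot.eps_virt_act], ref.scf.eps, atol=1e-9
        )


class TestLocality:
    def test_separated_dimer_active_orbitals_are_local(self):
        """One active monomer in a far-separated dimer: every active
        occupied orbital is >= 99% Mulliken-localized on the active atoms."""
        fx = make_fixture("dimer_separated")
        mol = fx.molecule
        ba = BasisAssignment(**fx.suggested_basis)
        ints, scf = compute_reference(mol, ba)
        shells = build_shells(mol, ba)
        sel = ActiveAtomSelection.from_atoms(shells, fx.suggested_active_atoms)
        C_act, _, _ = cholesky_partition_occupied(
            scf.density(), ints.S, sel, threshold=1e-2
        )
        active_aos = set(sel.ao_indices.tolist())
        SC = ints.S @ C_act
        for k in range(C_act.shape[1]):
            pops = SC[:, k] * C_act[:, k]
            frac = sum(pops[a] for a in active_aos) / pops.sum()
            assert frac > 0.99
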