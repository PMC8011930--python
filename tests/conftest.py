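"""Shared small-molecule references for the test suite.

Everything is generated at test time from the built-in integral engine; the
expensive objects are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from ccxas.basis import BasisAssignment
from ccxas.fixtures import make_fixture
from ccxas.moints import SpinOrbitalHamiltonian, mo_transform
from ccxas.molecule import load_geometry
from ccxas.scf import compute_reference


class Reference:
    """Bundle of AO/MO data for one molecule + basis."""

    def __init__(self, mol, basis):
        self.mol = mol
        self.basis = basis
        self.ints, self.scf = compute_reference(mol, basis)
        C = self.scf.C
        self.F_mo = C.T @ self.scf.fock_ao(self.ints) @ C
        self.h_mo = C.T @ self.ints.h @ C
        self.g_mo = mo_transform(self.ints.g, C)
        self.dip_mo = np.array([C.T @ self.ints.dipole[a] @ C for a in range(3)])

    def so_hamiltonian(self) -> SpinOrbitalHamiltonian:
        return SpinOrbitalHamiltonian.from_spatial(
            self.F_mo, self.g_mo, self.scf.n_occ,
            e_ref=self.scf.e_hf, dip_mo=self.dip_mo,
        )

    def so_dipoles(self):
        n = self.scf.n_mo
        m = np.zeros((3, 2 * n, 2 * n))
        for a in range(3):
            m[a][0::2, 0::2] = self.dip_mo[a]
            m[a][1::2, 1::2] = self.dip_mo[a]
        return m


H4_XYZ = "4\nbent H4 chain\nH 0 0 0\nH 0 0 0.9\nH 0 0.8 1.9\nH 0.1 0 2.8\n"


@pytest.fixture(scope="session")
def h2_sto3g():
    return Reference(make_fixture("h2").molecule, BasisAssignment("sto-3g"))


@pytest.fixture(scope="session")
def h2_631g():
    return Reference(make_fixture("h2").molecule, BasisAssignment("6-31g"))


@pytest.fixture(scope="session")
def h4_sto3g():
    return Reference(load_geometry(H4_XYZ), BasisAssignment("sto-3g"))


@pytest.fixture(scope="session")
def water_sto3g():
    return Reference(make_fixture("h2o").molecule, BasisAssignment("sto-3g"))


@pytest.fixture(scope="session")
def water_631g():
    return Reference(make_fixture("h2o").molecule, BasisAssignment("6-31g"))


@pytest.fixture(scope="session")
def h4_converged(h4_sto3g):
    from ccxas.ccsd import solve_amplitudes

    H = h4_sto3g.so_hamiltonian()
    state = solve_amplitudes(H, conv_tol=1e-10)
    return h4_sto3g, H, state


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_amplitude_vector(rng, no, nv, scale=1.0):
    r1 = scale * rng.standard_normal((no, nv))
    r2 = scale * rng.standard_normal((no, no, nv, nv))
    r2 = r2 - r2.transpose(1, 0, 2, 3)
    r2 = r2 - r2.transpose(0, 1, 3, 2)
    return r1, r2
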