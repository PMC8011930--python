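"""Closed-shell restricted Hartree-Fock with DIIS.

The reference is always a closed-shell RHF determinant; linear dependence in
the AO basis is removed by canonical orthonormalization of the overlap before
the SCF iterations, as required before any PAO construction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .basis import BasisAssignment, build_shells
from .integrals import AOIntegralSet, compute_ao_integrals
from .molecule import Molecule


class SCFConvergenceError(RuntimeError):
    def __init__(self, message: str, history: list[tuple[int, float, float]]):
        super().__init__(message)
        self.history = history


@dataclass
class SCFResult:
    """Converged RHF solution over the (linear-dependence-free) MO space."""

    C: np.ndarray            # (n_ao, n_mo) MO coefficients, C^T S C = 1
    eps: np.ndarray          # orbital energies
    n_occ: int               # doubly occupied orbital count
    e_hf: float              # total HF energy (Hartree)
    e_nuc: float
    converged: bool
    n_iter: int

    @property
    def n_mo(self) -> int:
        return self.C.shape[1]

    @property
    def C_occ(self) -> np.ndarray:
        return self.C[:, : self.n_occ]

    def density(self) -> np.ndarray:
        """Idempotent occupied density D = C_occ C_occ^T (per spin)."""
        return self.C_occ @ self.C_occ.T

    def fock_ao(self, ints: AOIntegralSet) -> np.ndarray:
        """AO Fock matrix rebuilt from the converged density."""
        D = self.density()
        J = np.einsum("pqrs,rs->pq", ints.g, D, optimize=True)
        K = np.einsum("prqs,rs->pq", ints.g, D, optimize=True)
        return ints.h + 2.0 * J - K


def canonical_orthonormalization(S: np.ndarray, lindep_tol: float = 1e-8) -> np.ndarray:
    """X with X^T S X = 1, dropping eigenvectors with metric eigenvalue below
    ``lindep_tol``."""
    w, U = np.linalg.eigh(S)
    keep = w > lindep_tol
    return U[:, keep] / np.sqrt(w[keep])


def solve_rhf(
    ints: AOIntegralSet,
    n_electrons: int,
    conv_tol: float = 1e-10,
    max_iter: int = 200,
    lindep_tol: float = 1e-8,
    diis_depth: int = 8,
) -> SCFResult:
    """Solve the closed-shell RHF equations (DIIS on the AO-basis error
    FDS - SDF)."""
    if n_electrons % 2 != 0:
        raise ValueError("open-shell reference requested; only closed-shell RHF is supported")
    n_occ = n_electrons // 2
    X = canonical_orthonormalization(ints.S, lindep_tol)
    h = ints.h
    S = ints.S
    g = ints.g

    # core guess
    e, C_ = np.linalg.eigh(X.T @ h @ X)
    C = X @ C_
    D = C[:, :n_occ] @ C[:, :n_occ].T

    errs: list[np.ndarray] = []
    focks: list[np.ndarray] = []
    history: list[tuple[int, float, float]] = []
    e_old = 0.0
    for it in range(1, max_iter + 1):
        J = np.einsum("pqrs,rs->pq", g, D, optimize=True)
        K = np.einsum("prqs,rs->pq", g, D, optimize=True)
        F = h + 2.0 * J - K
        e_elec = np.sum(D * (h + F))
        e_tot = e_elec + ints.e_nuc
        err = F @ D @ S - S @ D @ F
        err_norm = np.max(np.abs(err))
        history.append((it, e_tot, err_norm))
        if err_norm < conv_tol and abs(e_tot - e_old) < conv_tol:
            eps, C_ = np.linalg.eigh(X.T @ F @ X)
            C = X @ C_
            return SCFResult(C, eps, n_occ, e_tot, ints.e_nuc, True, it)
        e_old = e_tot

        errs.append(err)
        focks.append(F)
        if len(errs) > diis_depth:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            m = len(errs)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.sum(errs[i] * errs[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, focks))
            except np.linalg.LinAlgError:
                errs, focks = [errs[-1]], [focks[-1]]
        eps, C_ = np.linalg.eigh(X.T @ F @ X)
        C = X @ C_
        D = C[:, :n_occ] @ C[:, :n_occ].T

    raise SCFConvergenceError(
        f"RHF did not converge in {max_iter} iterations", history
    )


def compute_reference(
    molecule: Molecule,
    basis: BasisAssignment,
    conv_tol: float = 1e-10,
    lindep_tol: float = 1e-8,
) -> tuple[AOIntegralSet, SCFResult]:
    """Integrals plus a converged RHF reference for a molecule/basis pair."""
    shells = build_shells(molecule, basis)
    ints = compute_ao_integrals(molecule, shells)
    scf = solve_rhf(ints, molecule.n_electrons, conv_tol=conv_tol, lindep_tol=lindep_tol)
    return ints, scf
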