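"""Method drivers: CCSD, MLCCSD (CCS/CCSD) and CCSD-in-HF end to end.

Given AO integrals, an RHF reference and (for the multilevel methods) a
partitioned orbital space, these drivers build the spin-orbital Hamiltonian
in the appropriate basis, solve the ground state, and expose Jacobians for
the excited-state solvers.

Energy bookkeeping: MLCCSD works in the full semicanonical MO basis, so its
reference energy is the HF energy. CCSD-in-HF works in the truncated active
MO basis; the inactive occupied orbitals enter through the effective Fock
matrix (the active block of the full-density Fock operator) and the total
energy is reported as E_HF(full) + E_corr(active), which makes the
full-active limit agree with CCSD exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ccsd import (METHODS, ClusterState, doubles_mask, solve_amplitudes,
                   spatial_to_so_active)
from .eom import (CVSSpec, EOMState, GroundStateLambda, JacobianOperator,
                  biorthonormalize, davidson_solve, solve_multipliers)
from .integrals import AOIntegralSet
from .moints import SpinOrbitalHamiltonian, mo_transform
from .partition import OrbitalSpace, full_active_space
from .scf import SCFResult
from .spectra import TransitionRecord, transition_strengths


@dataclass
class EffectiveFock:
    """Active-space Fock matrix carrying the inactive-occupied mean field."""

    matrix: np.ndarray
    n_occ_inact: int

    @property
    def is_bare(self) -> bool:
        return self.n_occ_inact == 0


def build_effective_fock(F_ao: np.ndarray, space: OrbitalSpace) -> EffectiveFock:
    """Active block of the Fock operator built from the *full* density.

    Because F_ao already contains the Coulomb/exchange field of every
    occupied orbital, its active-active block is exactly the effective Fock
    matrix of the reduced-space method; with no inactive occupied orbitals
    it reduces to the bare active Fock block.
    """
    C_act = np.hstack([space.C_occ_act, space.C_virt_act])
    return EffectiveFock(
        matrix=C_act.T @ F_ao @ C_act, n_occ_inact=space.n_occ_inact
    )


@dataclass
class GroundStateResult:
    """Everything downstream solvers need: Hamiltonian, amplitudes, masks."""

    method: str
    H: SpinOrbitalHamiltonian
    state: ClusterState
    t2_mask: np.ndarray | None
    space: OrbitalSpace
    occ_active_spatial: np.ndarray  # over the spatial occupied list used


def _assemble_hamiltonian(
    ints: AOIntegralSet,
    scf: SCFResult,
    C: np.ndarray,
    n_occ: int,
    e_ref: float,
) -> SpinOrbitalHamiltonian:
    F_ao = scf.fock_ao(ints)
    F_mo = C.T @ F_ao @ C
    g_mo = mo_transform(ints.g, C)
    dip_mo = np.array([C.T @ ints.dipole[a] @ C for a in range(3)])
    return SpinOrbitalHamiltonian.from_spatial(
        F_mo, g_mo, n_occ, e_ref=e_ref, dip_mo=dip_mo
    )


def solve_ground_state(
    ints: AOIntegralSet,
    scf: SCFResult,
    method: str = "ccsd",
    space: OrbitalSpace | None = None,
    conv_tol: float = 1e-6,
    energy_tol: float = 1e-8,
    max_iter: int = 100,
) -> GroundStateResult:
    """Solve the requested ground-state model.

    ``space`` is required for mlccsd / ccsd-in-hf; for ccsd a partitioned
    space is accepted (the orbitals are a unitary within-occupied /
    within-virtual transform, leaving the CCSD solution invariant).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if space is None:
        if method != "ccsd":
            raise ValueError(f"{method} requires a partitioned orbital space")
        space = full_active_space(scf.C, scf.n_occ, scf.eps)

    if method == "ccsd-in-hf":
        C = np.hstack([space.C_occ_act, space.C_virt_act])
        n_occ = space.n_occ_act
        H = _assemble_hamiltonian(ints, scf, C, n_occ, e_ref=scf.e_hf)
        t2_mask = None
        occ_active = np.ones(n_occ, bool)
    else:
        C = space.C_full
        n_occ = space.n_occ
        H = _assemble_hamiltonian(ints, scf, C, n_occ, e_ref=scf.e_hf)
        occ_active = space.occ_active_flags
        if method == "mlccsd":
            t2_mask = doubles_mask(
                H.nocc, H.nvirt,
                spatial_to_so_active(space.occ_active_flags),
                spatial_to_so_active(space.virt_active_flags),
            )
        else:
            t2_mask = None
    state = solve_amplitudes(
        H, t2_mask=t2_mask, conv_tol=conv_tol, energy_tol=energy_tol,
        max_iter=max_iter, method=method,
    )
    return GroundStateResult(
        method=method, H=H, state=state, t2_mask=t2_mask, space=space,
        occ_active_spatial=occ_active,
    )


def make_cvs_spec(res: GroundStateResult, core_spatial_occ: list[int]) -> CVSSpec:
    """CVS specification from spatial occupied indices (calculation space)."""
    n_occ_sp = res.H.nocc // 2
    flags = np.zeros(n_occ_sp, bool)
    for i in core_spatial_occ:
        if not 0 <= i < n_occ_sp:
            raise ValueError(f"core orbital index {i} outside the occupied space")
        if res.t2_mask is not None and not res.occ_active_spatial[i]:
            raise ValueError(
                f"core orbital {i} must be an active occupied orbital"
            )
        flags[i] = True
    if not flags.any():
        raise ValueError("CVS specification must contain at least one core orbital")
    return CVSSpec.from_spatial(flags)


@dataclass
class ExcitedStatesResult:
    states: list[EOMState]
    lam: GroundStateLambda | None
    records: list[TransitionRecord]


def solve_excited_states(
    res: GroundStateResult,
    n_roots: int = 6,
    cvs: CVSSpec | None = None,
    res_tol: float = 1e-4,
    e_tol: float = 1e-6,
    with_oscillator_strengths: bool = True,
    max_iter: int = 150,
    spin: str = "singlet",
) -> ExcitedStatesResult:
    """Right and left CVS eigenstates, multipliers and oscillator strengths.

    By default only singlet roots are computed (triplets are dark in the
    absorption spectrum and are what "n roots per atom" counts in K-edge
    work); pass spin="both" to include them. The multiplier equations are
    solved without CVS (the ground state is a valence object); the
    excited-state projections carry the CVS spec.
    """
    op_cvs = JacobianOperator(
        res.H, res.state.t1, res.state.t2, t2_mask=res.t2_mask, cvs=cvs
    )
    rights = davidson_solve(
        op_cvs, n_roots, "right", res_tol=res_tol, e_tol=e_tol,
        max_iter=max_iter, spin=spin,
    )
    if not with_oscillator_strengths:
        # excitation energies only: the multipliers are not needed
        return ExcitedStatesResult(states=rights, lam=None, records=[])
    op_plain = JacobianOperator(
        res.H, res.state.t1, res.state.t2, t2_mask=res.t2_mask, cvs=None
    )
    lam = solve_multipliers(op_plain, conv_tol=1e-6)
    res.state.l1, res.state.l2 = lam.l1, lam.l2
    lefts = davidson_solve(
        op_cvs, n_roots, "left", res_tol=res_tol, e_tol=e_tol,
        max_iter=max_iter, spin=spin,
    )
    states = biorthonormalize(lefts, rights, lam)
    records = transition_strengths(
        states, lam, res.H, res.state.t1, res.state.t2, t2_mask=res.t2_mask
    )
    return ExcitedStatesResult(states=states, lam=lam, records=records)
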