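"""CCSD / MLCCSD / CCSD-in-HF ground states (spin-orbital formulation).

The cluster amplitudes solve the projected equations Omega_mu =
<mu|exp(-T) H exp(T)|HF> = 0. The multilevel CCS/CCSD model keeps T1 over
all orbitals but restricts T2 (and the doubles projection space) to active
orbitals; this is realized by masking the doubles amplitudes and residual
each iteration, which yields solutions identical to a dedicated restricted
solver. CCSD-in-HF is plain CCSD in a truncated active MO basis whose Fock
matrix carries the inactive-occupied mean field.

The working equations are the standard spin-orbital singles/doubles
equations with one- and two-body intermediates; the full (non-diagonal) Fock
matrix appears throughout, so semicanonical and reduced-space references are
handled without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .moints import SpinOrbitalHamiltonian

METHODS = ("ccsd", "mlccsd", "ccsd-in-hf")


class CCConvergenceError(RuntimeError):
    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


@dataclass
class ClusterState:
    """Converged cluster amplitudes and energies.

    ``t2_mask`` marks the allowed doubles space (None = all allowed); every
    amplitude outside it is identically zero.
    """

    t1: np.ndarray
    t2: np.ndarray
    e_corr: float
    e_total: float
    method: str
    converged: bool
    n_iter: int
    residual_norm: float
    t2_mask: np.ndarray | None = None
    l1: np.ndarray | None = None  # ground-state multipliers (set later)
    l2: np.ndarray | None = None


def _taus(t1, t2):
    x = np.einsum("ia,jb->ijab", t1, t1)
    x = x - x.transpose(0, 1, 3, 2)
    return t2 + 0.5 * x, t2 + x  # (tau_tilde, tau)


def ccsd_energy(H: SpinOrbitalHamiltonian, t1, t2) -> float:
    e = np.einsum("ia,ia->", H.f_ov, t1)
    e += 0.25 * np.einsum("ijab,ijab->", H.oovv, t2)
    e += 0.5 * np.einsum("ijab,ia,jb->", H.oovv, t1, t1, optimize=True)
    return float(e)


def ccsd_intermediates(H: SpinOrbitalHamiltonian, t1, t2):
    """One- and two-body intermediates of the singles/doubles equations."""
    tau_t, tau = _taus(t1, t2)
    Fae = (
        H.f_vv
        - 0.5 * np.einsum("ma,me->ae", t1, H.f_ov)
        + np.einsum("mf,mafe->ae", t1, H.ovvv, optimize=True)
        - 0.5 * np.einsum("mnaf,mnef->ae", tau_t, H.oovv, optimize=True)
    )
    Fmi = (
        H.f_oo
        + 0.5 * np.einsum("ie,me->mi", t1, H.f_ov)
        + np.einsum("ne,mnie->mi", t1, H.ooov, optimize=True)
        + 0.5 * np.einsum("inef,mnef->mi", tau_t, H.oovv, optimize=True)
    )
    Fme = H.f_ov + np.einsum("nf,mnef->me", t1, H.oovv, optimize=True)

    Wmnij = H.oooo + _pij(
        np.einsum("je,mnie->mnij", t1, H.ooov, optimize=True), (2, 3)
    )
    Wmnij = Wmnij + 0.25 * np.einsum("ijef,mnef->mnij", tau, H.oovv, optimize=True)

    # <am||ef> = -<ma||ef>
    Wabef = H.vvvv - _pij(
        -np.einsum("mb,maef->abef", t1, H.ovvv, optimize=True), (0, 1)
    )
    Wabef = Wabef + 0.25 * np.einsum("mnab,mnef->abef", tau, H.oovv, optimize=True)

    # <mb||ej> = -<mb||je>; <mn||ej> = -<mn||je>
    Wmbej = (
        -H.ovov.transpose(0, 1, 3, 2)
        + np.einsum("jf,mbef->mbej", t1, H.ovvv, optimize=True)
        + np.einsum("nb,mnje->mbej", t1, H.ooov, optimize=True)
        - np.einsum("jnfb,mnef->mbej", 0.5 * t2, H.oovv, optimize=True)
        - np.einsum("jf,nb,mnef->mbej", t1, t1, H.oovv, optimize=True)
    )
    return Fae, Fmi, Fme, Wmnij, Wabef, Wmbej, tau


def _pij(x, axes):
    """Antisymmetrizer P(ij): x - x with the two axes swapped."""
    perm = list(range(x.ndim))
    perm[axes[0]], perm[axes[1]] = perm[axes[1]], perm[axes[0]]
    return x - x.transpose(perm)


def ccsd_residual(H: SpinOrbitalHamiltonian, t1, t2, t2_mask=None):
    """Residual vectors (Omega1, Omega2); zero at the solution.

    With ``t2_mask`` set (MLCCSD), the input T2 must vanish outside the mask
    and the doubles residual is projected onto the mask, which is the
    restriction of the doubles projection space to the active orbitals.
    """
    if t2_mask is not None and np.any(np.abs(t2[~t2_mask]) > 1e-12):
        raise ValueError("T2 has weight outside the allowed active-space pattern")
    Fae, Fmi, Fme, Wmnij, Wabef, Wmbej, tau = ccsd_intermediates(H, t1, t2)

    o1 = (
        H.f_ov
        + np.einsum("ie,ae->ia", t1, Fae)
        - np.einsum("ma,mi->ia", t1, Fmi)
        + np.einsum("imae,me->ia", t2, Fme, optimize=True)
        - np.einsum("nf,naif->ia", t1, H.ovov, optimize=True)
        - 0.5 * np.einsum("imef,maef->ia", t2, H.ovvv, optimize=True)
        + 0.5 * np.einsum("mnae,nmie->ia", t2, H.ooov, optimize=True)
    )

    Fbe_eff = Fae - 0.5 * np.einsum("mb,me->be", t1, Fme)
    Fmj_eff = Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme)
    o2 = H.oovv.copy()
    o2 += _pij(np.einsum("ijae,be->ijab", t2, Fbe_eff, optimize=True), (2, 3))
    o2 -= _pij(np.einsum("imab,mj->ijab", t2, Fmj_eff, optimize=True), (0, 1))
    o2 += 0.5 * np.einsum("mnab,mnij->ijab", tau, Wmnij, optimize=True)
    o2 += 0.5 * np.einsum("ijef,abef->ijab", tau, Wabef, optimize=True)
    ring = np.einsum("imae,mbej->ijab", t2, Wmbej, optimize=True)
    # - t1 t1 <mb||ej> ; <mb||ej> = -<mb||je>
    ring += np.einsum("ie,ma,mbje->ijab", t1, t1, H.ovov, optimize=True)
    o2 += _pij(_pij(ring, (0, 1)), (2, 3))
    # P(ij) t1_ie <ab||ej>; <ab||ej> = -<je||ab>
    o2 += _pij(
        -np.einsum("ie,jeab->ijab", t1, H.ovvv.transpose(0, 1, 2, 3), optimize=True),
        (0, 1),
    )
    # - P(ab) t1_ma <mb||ij>; <mb||ij> = <ij||mb>
    o2 -= _pij(np.einsum("ma,ijmb->ijab", t1, H.ooov, optimize=True), (2, 3))

    if t2_mask is not None:
        o2 = np.where(t2_mask, o2, 0.0)
    return o1, o2


def residual_norm(o1, o2) -> float:
    """Norm consistent with the unique-amplitude inner product."""
    return float(np.sqrt(np.sum(o1 * o1) + 0.25 * np.sum(o2 * o2)))


def mp2_guess(H: SpinOrbitalHamiltonian, t2_mask=None):
    d1, d2 = H.denominators()
    t1 = np.zeros_like(H.f_ov)
    t2 = H.oovv / d2
    if t2_mask is not None:
        t2 = np.where(t2_mask, t2, 0.0)
    return t1, t2


class _DIIS:
    """Pulay mixing over concatenated amplitude/error vectors."""

    def __init__(self, depth=8):
        self.depth = depth
        self.ts: list[np.ndarray] = []
        self.errs: list[np.ndarray] = []

    def extrapolate(self, t_flat, err_flat):
        self.ts.append(t_flat)
        self.errs.append(err_flat)
        if len(self.ts) > self.depth:
            self.ts.pop(0)
            self.errs.pop(0)
        m = len(self.ts)
        if m < 2:
            return t_flat
        B = np.empty((m + 1, m + 1))
        B[:m, :m] = np.array(
            [[e1 @ e2 for e2 in self.errs] for e1 in self.errs]
        )
        B[m, :] = -1.0
        B[:, m] = -1.0
        B[m, m] = 0.0
        rhs = np.zeros(m + 1)
        rhs[m] = -1.0
        try:
            w = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            self.ts, self.errs = [self.ts[-1]], [self.errs[-1]]
            return t_flat
        return sum(wi * ti for wi, ti in zip(w, self.ts))


def solve_amplitudes(
    H: SpinOrbitalHamiltonian,
    t2_mask: np.ndarray | None = None,
    conv_tol: float = 1e-6,
    energy_tol: float = 1e-8,
    max_iter: int = 100,
    diis_depth: int = 8,
    method: str = "ccsd",
) -> ClusterState:
    """Iterate the amplitude equations to ||Omega|| < conv_tol (quasi-Newton
    with semicanonical denominators, DIIS acceleration)."""
    d1, d2 = H.denominators()
    t1, t2 = mp2_guess(H, t2_mask)
    n1 = t1.size
    diis = _DIIS(diis_depth)
    history = []
    e_old = ccsd_energy(H, t1, t2)
    for it in range(1, max_iter + 1):
        o1, o2 = ccsd_residual(H, t1, t2, t2_mask)
        rn = residual_norm(o1, o2)
        e = ccsd_energy(H, t1, t2)
        history.append((it, e, rn))
        if rn < conv_tol and abs(e - e_old) < energy_tol:
            return ClusterState(
                t1=t1, t2=t2, e_corr=e, e_total=H.e_ref + e, method=method,
                converged=True, n_iter=it, residual_norm=rn, t2_mask=t2_mask,
            )
        e_old = e
        dt1 = o1 / d1
        dt2 = o2 / d2
        if t2_mask is not None:
            dt2 = np.where(t2_mask, dt2, 0.0)
        t_new = np.concatenate([(t1 + dt1).ravel(), (t2 + dt2).ravel()])
        err = np.concatenate([dt1.ravel(), dt2.ravel()])
        t_new = diis.extrapolate(t_new, err)
        t1 = t_new[:n1].reshape(t1.shape)
        t2 = t_new[n1:].reshape(t2.shape)
        if t2_mask is not None:
            t2 = np.where(t2_mask, t2, 0.0)
    raise CCConvergenceError(
        f"amplitude equations not converged in {max_iter} iterations "
        f"(last ||Omega|| = {history[-1][2]:.3e})",
        history,
    )


def doubles_mask(nocc_so, nvirt_so, occ_active, virt_active) -> np.ndarray:
    """Boolean (o,o,v,v) mask: all four spin-orbital indices active.

    ``occ_active`` / ``virt_active`` are boolean arrays over the spin-orbital
    occupied / virtual lists.
    """
    oa = np.asarray(occ_active, bool)
    va = np.asarray(virt_active, bool)
    return (
        oa[:, None, None, None] & oa[None, :, None, None]
        & va[None, None, :, None] & va[None, None, None, :]
    )


def spatial_to_so_active(active_spatial: np.ndarray) -> np.ndarray:
    """Expand a spatial-orbital activity flag to interleaved spin orbitals."""
    return np.repeat(np.asarray(active_spatial, bool), 2)
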