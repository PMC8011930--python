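"""Equation-of-motion excited states for CCSD / MLCCSD / CCSD-in-HF.

The Jacobian A_{mu,nu} = <mu|[Hbar, tau_nu]|HF> is applied matrix-free as
the exact directional derivative of the ground-state residual: A r =
d/ds Omega(t + s r)|_{s=0}, expanded analytically through the same one- and
two-body intermediates the residual uses. The transpose action is the
corresponding reverse-mode (adjoint) accumulation, so left and right
transformations are adjoint with respect to the amplitude inner product

    <x, y> = sum x1 y1 + 1/4 sum x2 y2

(the 1/4 compensating the redundancy of the antisymmetrized doubles
storage). Core-valence separation is realized by projecting trial vectors,
residuals and preconditioned corrections: every singles element whose
occupied index is not a core orbital, and every doubles element with neither
occupied index in the core set, is zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .ccsd import ccsd_intermediates, ccsd_residual, residual_norm, _pij
from .moints import SpinOrbitalHamiltonian


# ---------------------------------------------------------------------------
# amplitude-space vectors
# ---------------------------------------------------------------------------


def cc_dot(x, y) -> float:
    """Inner product over unique amplitudes (1/4 weight on full doubles)."""
    return float(np.sum(x[0] * y[0]) + 0.25 * np.sum(x[1] * y[1]))


def cc_norm(x) -> float:
    return float(np.sqrt(cc_dot(x, x)))


def antisymmetrize_doubles(x2: np.ndarray) -> np.ndarray:
    return 0.25 * (
        x2 - x2.transpose(1, 0, 2, 3) - x2.transpose(0, 1, 3, 2)
        + x2.transpose(1, 0, 3, 2)
    )


@dataclass
class CVSSpec:
    """Core-valence separation: which occupied spin orbitals are core."""

    core_occ: np.ndarray  # boolean over occupied spin orbitals

    @classmethod
    def from_spatial(cls, core_spatial: np.ndarray) -> "CVSSpec":
        return cls(np.repeat(np.asarray(core_spatial, bool), 2))


def cvs_project(x, spec: CVSSpec | None):
    """Zero every element without a core occupied index (idempotent)."""
    if spec is None:
        return x
    c = spec.core_occ
    r1 = np.where(c[:, None], x[0], 0.0)
    keep = c[:, None, None, None] | c[None, :, None, None]
    r2 = np.where(keep, x[1], 0.0)
    return (r1, r2)


# ---------------------------------------------------------------------------
# Jacobian operator
# ---------------------------------------------------------------------------


class JacobianOperator:
    """Matrix-free (ML)CCSD Jacobian built on converged amplitudes.

    ``t2_mask`` restricts the doubles rows/columns (MLCCSD); ``cvs``
    restricts the whole vector space to core-labelled excitations.
    """

    def __init__(
        self,
        H: SpinOrbitalHamiltonian,
        t1: np.ndarray,
        t2: np.ndarray,
        t2_mask: np.ndarray | None = None,
        cvs: CVSSpec | None = None,
    ):
        self.H = H
        self.t1 = t1
        self.t2 = t2
        self.t2_mask = t2_mask
        self.cvs = cvs
        (self.Fae, self.Fmi, self.Fme, self.Wmnij, self.Wabef,
         self.Wmbej, self.tau) = ccsd_intermediates(H, t1, t2)
        self.Fbe_eff = self.Fae - 0.5 * np.einsum("mb,me->be", t1, self.Fme)
        self.Fmj_eff = self.Fmi + 0.5 * np.einsum("je,me->mj", t1, self.Fme)

    # -- vector hygiene ----------------------------------------------------
    def project(self, x):
        r1, r2 = cvs_project(x, self.cvs)
        if self.t2_mask is not None:
            r2 = np.where(self.t2_mask, r2, 0.0)
        return (r1, r2)

    @property
    def shape1(self):
        return self.t1.shape

    @property
    def shape2(self):
        return self.t2.shape

    def diagonal_denominators(self):
        """Orbital-energy-difference approximations to diag(A)."""
        eo = self.H.eps_occ
        ev = self.H.eps_virt
        d1 = ev[None, :] - eo[:, None]
        d2 = (
            ev[None, None, :, None] + ev[None, None, None, :]
            - eo[:, None, None, None] - eo[None, :, None, None]
        )
        return d1, d2

    # -- forward (right) transformation ------------------------------------
    def apply(self, x):
        """A x as the directional derivative of the residual at t."""
        r1, r2 = self.project(x)
        H, t1, t2 = self.H, self.t1, self.t2
        Fae, Fmi, Fme = self.Fae, self.Fmi, self.Fme
        Wmnij, Wabef, Wmbej, tau = self.Wmnij, self.Wabef, self.Wmbej, self.tau

        sym = np.einsum("ia,jb->ijab", r1, t1) + np.einsum("ia,jb->ijab", t1, r1)
        sym = sym - sym.transpose(0, 1, 3, 2)
        dtau = r2 + sym
        dtau_t = r2 + 0.5 * sym

        dFae = (
            -0.5 * np.einsum("ma,me->ae", r1, H.f_ov)
            + np.einsum("mf,mafe->ae", r1, H.ovvv, optimize=True)
            - 0.5 * np.einsum("mnaf,mnef->ae", dtau_t, H.oovv, optimize=True)
        )
        dFmi = (
            0.5 * np.einsum("ie,me->mi", r1, H.f_ov)
            + np.einsum("ne,mnie->mi", r1, H.ooov, optimize=True)
            + 0.5 * np.einsum("inef,mnef->mi", dtau_t, H.oovv, optimize=True)
        )
        dFme = np.einsum("nf,mnef->me", r1, H.oovv, optimize=True)

        s1 = (
            np.einsum("ie,ae->ia", r1, Fae)
            + np.einsum("ie,ae->ia", t1, dFae)
            - np.einsum("ma,mi->ia", r1, Fmi)
            - np.einsum("ma,mi->ia", t1, dFmi)
            + np.einsum("imae,me->ia", r2, Fme, optimize=True)
            + np.einsum("imae,me->ia", t2, dFme, optimize=True)
            - np.einsum("nf,naif->ia", r1, H.ovov, optimize=True)
            - 0.5 * np.einsum("imef,maef->ia", r2, H.ovvv, optimize=True)
            + 0.5 * np.einsum("mnae,nmie->ia", r2, H.ooov, optimize=True)
        )

        dWmnij = _pij(
            np.einsum("je,mnie->mnij", r1, H.ooov, optimize=True), (2, 3)
        ) + 0.25 * np.einsum("ijef,mnef->mnij", dtau, H.oovv, optimize=True)
        dWabef = _pij(
            np.einsum("mb,maef->abef", r1, H.ovvv, optimize=True), (0, 1)
        ) + 0.25 * np.einsum("mnab,mnef->abef", dtau, H.oovv, optimize=True)
        dWmbej = (
            np.einsum("jf,mbef->mbej", r1, H.ovvv, optimize=True)
            + np.einsum("nb,mnje->mbej", r1, H.ooov, optimize=True)
            - np.einsum("jnfb,mnef->mbej", 0.5 * r2, H.oovv, optimize=True)
            - np.einsum("jf,nb,mnef->mbej", r1, t1, H.oovv, optimize=True)
            - np.einsum("jf,nb,mnef->mbej", t1, r1, H.oovv, optimize=True)
        )
        dFbe_eff = dFae - 0.5 * (
            np.einsum("mb,me->be", r1, Fme) + np.einsum("mb,me->be", t1, dFme)
        )
        dFmj_eff = dFmi + 0.5 * (
            np.einsum("je,me->mj", r1, Fme) + np.einsum("je,me->mj", t1, dFme)
        )

        s2 = _pij(
            np.einsum("ijae,be->ijab", r2, self.Fbe_eff, optimize=True)
            + np.einsum("ijae,be->ijab", t2, dFbe_eff, optimize=True),
            (2, 3),
        )
        s2 -= _pij(
            np.einsum("imab,mj->ijab", r2, self.Fmj_eff, optimize=True)
            + np.einsum("imab,mj->ijab", t2, dFmj_eff, optimize=True),
            (0, 1),
        )
        s2 += 0.5 * np.einsum("mnab,mnij->ijab", dtau, Wmnij, optimize=True)
        s2 += 0.5 * np.einsum("mnab,mnij->ijab", tau, dWmnij, optimize=True)
        s2 += 0.5 * np.einsum("ijef,abef->ijab", dtau, Wabef, optimize=True)
        s2 += 0.5 * np.einsum("ijef,abef->ijab", tau, dWabef, optimize=True)
        ring = (
            np.einsum("imae,mbej->ijab", r2, Wmbej, optimize=True)
            + np.einsum("imae,mbej->ijab", t2, dWmbej, optimize=True)
            + np.einsum("ie,ma,mbje->ijab", r1, t1, H.ovov, optimize=True)
            + np.einsum("ie,ma,mbje->ijab", t1, r1, H.ovov, optimize=True)
        )
        s2 += _pij(_pij(ring, (0, 1)), (2, 3))
        s2 += _pij(-np.einsum("ie,jeab->ijab", r1, H.ovvv, optimize=True), (0, 1))
        s2 -= _pij(np.einsum("ma,ijmb->ijab", r1, H.ooov, optimize=True), (2, 3))

        return self.project((s1, s2))

    # -- adjoint (left) transformation -------------------------------------
    def apply_transpose(self, x):
        """A^T x via reverse-mode accumulation through the intermediates."""
        w1, w2 = self.project(x)
        H, t1, t2 = self.H, self.t1, self.t2
        Fme = self.Fme

        # adjoints of intermediates from their direct appearances
        Fae_b = np.einsum("ia,ie->ae", w1, t1)
        Fmi_b = -np.einsum("ia,ma->mi", w1, t1)
        Fme_b = np.einsum("ia,imae->me", w1, t2, optimize=True)

        t1_b = (
            np.einsum("ia,ae->ie", w1, self.Fae)
            - np.einsum("ia,mi->ma", w1, self.Fmi)
            - np.einsum("ia,naif->nf", w1, H.ovov, optimize=True)
        )
        t2_b = (
            np.einsum("ia,me->imae", w1, Fme)
            - 0.5 * np.einsum("ia,maef->imef", w1, H.ovvv, optimize=True)
            + 0.5 * np.einsum("ia,nmie->mnae", w1, H.ooov, optimize=True)
        )

        # doubles equation couplings (P operators folded into w2 antisymmetry)
        Fbe_eff_b = 0.5 * np.einsum("ijab,ijae->be", w2, t2, optimize=True)
        t2_b += 0.5 * np.einsum("ijab,be->ijae", w2, self.Fbe_eff, optimize=True)
        Fmj_eff_b = -0.5 * np.einsum("ijab,imab->mj", w2, t2, optimize=True)
        t2_b -= 0.5 * np.einsum("ijab,mj->imab", w2, self.Fmj_eff, optimize=True)

        Fae_b += Fbe_eff_b
        Fme_b -= 0.5 * np.einsum("mb,be->me", t1, Fbe_eff_b)
        t1_b -= 0.5 * np.einsum("be,me->mb", Fbe_eff_b, Fme)
        Fmi_b += Fmj_eff_b
        Fme_b += 0.5 * np.einsum("je,mj->me", t1, Fmj_eff_b)
        t1_b += 0.5 * np.einsum("mj,me->je", Fmj_eff_b, Fme)

        tau_b = 0.125 * np.einsum("ijab,mnij->mnab", w2, self.Wmnij, optimize=True)
        Wmnij_b = 0.125 * np.einsum("ijab,mnab->mnij", w2, self.tau, optimize=True)
        tau_b += 0.125 * np.einsum("ijab,abef->ijef", w2, self.Wabef, optimize=True)
        Wabef_b = 0.125 * np.einsum("ijab,ijef->abef", w2, self.tau, optimize=True)

        Wmbej_b = np.einsum("ijab,imae->mbej", w2, t2, optimize=True)
        t2_b += np.einsum("ijab,mbej->imae", w2, self.Wmbej, optimize=True)
        t1_b += np.einsum("ijab,ma,mbje->ie", w2, t1, H.ovov, optimize=True)
        t1_b += np.einsum("ijab,ie,mbje->ma", w2, t1, H.ovov, optimize=True)
        t1_b -= 0.5 * np.einsum("ijab,jeab->ie", w2, H.ovvv, optimize=True)
        t1_b -= 0.5 * np.einsum("ijab,ijmb->ma", w2, H.ooov, optimize=True)

        # propagate intermediate adjoints into t1/t2/tau adjoints
        tau_t_b = np.zeros_like(t2)
        t1_b -= 0.5 * np.einsum("ae,me->ma", Fae_b, H.f_ov)
        t1_b += np.einsum("ae,mafe->mf", Fae_b, H.ovvv, optimize=True)
        tau_t_b -= 0.5 * np.einsum("ae,mnef->mnaf", Fae_b, H.oovv, optimize=True)

        t1_b += 0.5 * np.einsum("mi,me->ie", Fmi_b, H.f_ov)
        t1_b += np.einsum("mi,mnie->ne", Fmi_b, H.ooov, optimize=True)
        tau_t_b += 0.5 * np.einsum("mi,mnef->inef", Fmi_b, H.oovv, optimize=True)

        t1_b += np.einsum("me,mnef->nf", Fme_b, H.oovv, optimize=True)

        WmnijA = Wmnij_b - Wmnij_b.transpose(0, 1, 3, 2)
        t1_b += np.einsum("mnij,mnie->je", WmnijA, H.ooov, optimize=True)
        tau_b += 0.25 * np.einsum("mnij,mnef->ijef", Wmnij_b, H.oovv, optimize=True)

        WabefA = Wabef_b - Wabef_b.transpose(1, 0, 2, 3)
        t1_b += np.einsum("abef,maef->mb", WabefA, H.ovvv, optimize=True)
        tau_b += 0.25 * np.einsum("abef,mnef->mnab", Wabef_b, H.oovv, optimize=True)

        t1_b += np.einsum("mbej,mbef->jf", Wmbej_b, H.ovvv, optimize=True)
        t1_b -= np.einsum("mbej,nb,mnef->jf", Wmbej_b, t1, H.oovv, optimize=True)
        t1_b += np.einsum("mbej,mnje->nb", Wmbej_b, H.ooov, optimize=True)
        t1_b -= np.einsum("mbej,jf,mnef->nb", Wmbej_b, t1, H.oovv, optimize=True)
        t2_b -= 0.5 * np.einsum("mbej,mnef->jnfb", Wmbej_b, H.oovv, optimize=True)

        # tau = t2 + t1 ^ t1 ; tau_tilde = t2 + (t1 ^ t1) / 2
        t2_b += tau_b + tau_t_b
        for tb, fac in ((tau_b, 1.0), (tau_t_b, 0.5)):
            t1_b += fac * (
                np.einsum("pjqb,jb->pq", tb, t1, optimize=True)
                + np.einsum("ipaq,ia->pq", tb, t1, optimize=True)
                - np.einsum("pjbq,jb->pq", tb, t1, optimize=True)
                - np.einsum("ipqb,ib->pq", tb, t1, optimize=True)
            )

        s2 = 4.0 * antisymmetrize_doubles(t2_b)
        return self.project((t1_b, s2))

    def dense_matrix(self):
        """Explicit A (unique-amplitude basis), for small-system tests."""
        no, nv = self.shape1
        singles = [(i, a) for i in range(no) for a in range(nv)]
        doubles = [
            (i, j, a, b)
            for i in range(no) for j in range(i + 1, no)
            for a in range(nv) for b in range(a + 1, nv)
        ]
        dim = len(singles) + len(doubles)
        A = np.zeros((dim, dim))
        for col in range(dim):
            x = unit_vector(no, nv, singles, doubles, col)
            s = self.apply(x)
            A[:, col] = pack_unique(s, singles, doubles)
        return A


def unit_vector(no, nv, singles, doubles, k):
    r1 = np.zeros((no, nv))
    r2 = np.zeros((no, no, nv, nv))
    if k < len(singles):
        i, a = singles[k]
        r1[i, a] = 1.0
    else:
        i, j, a, b = doubles[k - len(singles)]
        r2[i, j, a, b] = 1.0
        r2[j, i, a, b] = -1.0
        r2[i, j, b, a] = -1.0
        r2[j, i, b, a] = 1.0
    return (r1, r2)


def pack_unique(x, singles, doubles):
    r1, r2 = x
    out = np.empty(len(singles) + len(doubles))
    for k, (i, a) in enumerate(singles):
        out[k] = r1[i, a]
    for k, (i, j, a, b) in enumerate(doubles):
        out[len(singles) + k] = r2[i, j, a, b]
    return out


# ---------------------------------------------------------------------------
# eta vector, multipliers
# ---------------------------------------------------------------------------


def eta_vector(H: SpinOrbitalHamiltonian, t1, t2):
    """eta_nu = <HF|[Hbar, tau_nu]|HF> (the energy gradient)."""
    eta1 = H.f_ov + np.einsum("ijab,jb->ia", H.oovv, t1, optimize=True)
    return (eta1, H.oovv.copy())


@dataclass
class GroundStateLambda:
    """Ground-state multipliers l0 solving l0^T A = -eta."""

    l1: np.ndarray
    l2: np.ndarray
    residual: float
    converged: bool


def solve_multipliers(
    op: JacobianOperator,
    conv_tol: float = 1e-6,
    max_iter: int = 200,
    diis_depth: int = 8,
) -> GroundStateLambda:
    """Solve A^T l = -eta by preconditioned iteration with DIIS.

    The operator must be built without CVS (the ground state is a valence
    object); for MLCCSD the doubles mask applies.
    """
    if op.cvs is not None:
        raise ValueError("multiplier equations are solved without CVS")
    eta = eta_vector(op.H, op.t1, op.t2)
    eta = op.project(eta)
    d1, d2 = op.diagonal_denominators()
    l1 = eta[0] / d1
    l2 = eta[1] / np.where(d2 == 0.0, 1.0, d2)
    l2 = op.project((l1, l2))[1]
    from .ccsd import _DIIS

    diis = _DIIS(diis_depth)
    n1 = l1.size
    for _ in range(max_iter):
        Atl = op.apply_transpose((l1, l2))
        R = (Atl[0] + eta[0], Atl[1] + eta[1])
        rn = cc_norm(R)
        if rn < conv_tol:
            return GroundStateLambda(l1, l2, rn, True)
        dl1 = -R[0] / d1
        dl2 = -R[1] / np.where(d2 == 0.0, 1.0, d2)
        if op.t2_mask is not None:
            dl2 = np.where(op.t2_mask, dl2, 0.0)
        new = np.concatenate([(l1 + dl1).ravel(), (l2 + dl2).ravel()])
        err = np.concatenate([dl1.ravel(), dl2.ravel()])
        new = diis.extrapolate(new, err)
        l1 = new[:n1].reshape(l1.shape)
        l2 = new[n1:].reshape(l2.shape)
        l2 = op.project((l1, l2))[1]
    raise RuntimeError(
        f"multiplier equations not converged (residual {rn:.3e})"
    )


# ---------------------------------------------------------------------------
# Davidson eigensolver
# ---------------------------------------------------------------------------


@dataclass
class EOMState:
    """One EOM eigenstate (right and, once attached, left vector)."""

    omega: float  # Hartree
    r1: np.ndarray
    r2: np.ndarray
    residual: float
    l1: np.ndarray | None = None
    l2: np.ndarray | None = None
    left_residual: float | None = None
    r0: float = 0.0
    biorthonormalized: bool = False


class DavidsonError(RuntimeError):
    def __init__(self, message, states):
        super().__init__(message)
        self.states = states


def _singlet_adapt(x, occA, occB, virt):
    """Project onto the Sz = 0, spin-flip-even (singlet-containing) sector.

    ``occA``/``occB``/``virt`` are (spin array, flip permutation) pairs for
    the two occupied axes and the virtual axes. Because the similarity-
    transformed Hamiltonian over a closed-shell reference is spin-free, this
    sector is invariant under the Jacobian, so projecting guesses and
    corrections keeps the whole iteration in the singlet space.
    """
    (sA, pA), (sB, pB), (sv, pv) = occA, occB, virt
    r1, r2 = x
    m1 = sA[:, None] == sv[None, :]
    r1 = np.where(m1, r1, 0.0)
    r1 = 0.5 * (r1 + r1[np.ix_(pA, pv)])
    m2 = (
        sA[:, None, None, None] + sB[None, :, None, None]
        == sv[None, None, :, None] + sv[None, None, None, :]
    )
    r2 = np.where(m2, r2, 0.0)
    r2 = 0.5 * (r2 + r2[np.ix_(pA, pB, pv, pv)])
    return (r1, r2)


class _FullVectorSpace:
    """Amplitude vectors as full (r1, r2) arrays."""

    def __init__(self, op: JacobianOperator, side: str, spin: str = "both"):
        self.op = op
        self.spin = spin
        self._apply = op.apply if side == "right" else op.apply_transpose
        no, nv = op.shape1
        self.no, self.nv = no, nv
        mask1 = np.ones((no, nv), bool)
        if op.cvs is not None:
            mask1 &= op.cvs.core_occ[:, None]
        self.window = np.flatnonzero(mask1.ravel())  # allowed singles
        so = np.arange(no) % 2
        sv = np.arange(nv) % 2
        self._spin_axes = ((so, np.arange(no) ^ 1), (so, np.arange(no) ^ 1),
                           (sv, np.arange(nv) ^ 1))

    def dot(self, x, y) -> float:
        return cc_dot(x, y)

    def norm(self, x) -> float:
        return float(np.sqrt(self.dot(x, x)))

    def apply(self, x):
        return self._apply(x)

    def project(self, x):
        x = self.op.project(x)
        if self.spin == "singlet":
            x = _singlet_adapt(x, *self._spin_axes)
        return x

    def unpack(self, x):
        return x

    def singles_guess(self, coefs: np.ndarray):
        r1 = np.zeros(self.no * self.nv)
        r1[self.window] = coefs
        return self.project(
            (r1.reshape(self.no, self.nv), np.zeros(self.op.shape2))
        )

    def denominators(self):
        return self.op.diagonal_denominators()


class _CVSCompressedSpace:
    """CVS amplitude vectors stored on core rows only.

    A CVS vector has nonzero singles only on core occupied rows and nonzero
    doubles only when an occupied index is core; by antisymmetry the blocks
    r2[core, :, :, :] determine the whole doubles part. Storing just those
    rows shrinks the vectors by roughly (n_occ / n_core) and makes the
    subspace algebra of the eigensolver essentially free.
    """

    def __init__(self, op: JacobianOperator, side: str, spin: str = "both"):
        self.op = op
        self.spin = spin
        self._apply = op.apply if side == "right" else op.apply_transpose
        no, nv = op.shape1
        self.no, self.nv = no, nv
        self.core = np.flatnonzero(op.cvs.core_occ)
        nc = len(self.core)
        if spin == "singlet":
            # flip permutation within the core-row list
            flip_so = {so: k for k, so in enumerate(self.core)}
            if any((so ^ 1) not in flip_so for so in self.core):
                raise ValueError(
                    "singlet CVS window requires both spins of each core orbital"
                )
            cperm = np.array([flip_so[so ^ 1] for so in self.core])
            self._spin_axes = (
                (self.core % 2, cperm),
                (np.arange(no) % 2, np.arange(no) ^ 1),
                (np.arange(nv) % 2, np.arange(nv) ^ 1),
            )
        is_core = np.zeros(no, bool)
        is_core[self.core] = True
        # weight 1 for core second index (counted once), 2 otherwise (the
        # mirrored (j, i) element carries the same product)
        self.w2 = np.where(is_core, 1.0, 2.0)[None, :, None, None]
        self.mask2 = (
            None if op.t2_mask is None else op.t2_mask[self.core]
        )
        mask1 = np.ones((nc, nv), bool)
        self.window = np.arange(nc * nv)

    def pack(self, x):
        return (x[0][self.core].copy(), x[1][self.core].copy())

    def unpack(self, xc):
        p1, p2 = xc
        r1 = np.zeros((self.no, self.nv))
        r1[self.core] = p1
        r2 = np.zeros((self.no, self.no, self.nv, self.nv))
        r2[:, self.core] = -p2.transpose(1, 0, 2, 3)
        r2[self.core] = p2
        return (r1, r2)

    def dot(self, x, y) -> float:
        return float(
            np.sum(x[0] * y[0]) + 0.25 * np.sum(self.w2 * x[1] * y[1])
        )

    def norm(self, x) -> float:
        return float(np.sqrt(self.dot(x, x)))

    def apply(self, xc):
        return self.pack(self._apply(self.unpack(xc)))

    def project(self, xc):
        if self.mask2 is not None:
            xc = (xc[0], np.where(self.mask2, xc[1], 0.0))
        if self.spin == "singlet":
            xc = _singlet_adapt(xc, *self._spin_axes)
        return xc

    def singles_guess(self, coefs: np.ndarray):
        nc = len(self.core)
        return self.project(
            (coefs.reshape(nc, self.nv).copy(),
             np.zeros((nc, self.no, self.nv, self.nv)))
        )

    def denominators(self):
        d1, d2 = self.op.diagonal_denominators()
        return d1[self.core], d2[self.core]


def davidson_solve(
    op: JacobianOperator,
    n_roots: int,
    side: str = "right",
    res_tol: float = 1e-4,
    e_tol: float = 1e-6,
    max_iter: int = 120,
    max_space: int | None = None,
    verbose: bool = False,
    cluster_tol: float = 1e-5,
    spin: str = "both",
) -> list[EOMState]:
    """Lowest eigenpairs of A (or A^T) within the projected space.

    Start guesses are the eigenvectors of the singles-singles block
    restricted to the allowed (CVS-projected) window, which anchors the
    root tracking to the physical core-excitation states. Because the
    projected Jacobian is strongly non-normal, three safeguards are used:

    * roots are followed across iterations by projection onto the span of
      the previous Ritz vectors (never by "lowest eigenvalue", which locks
      onto spurious oblique-projection ghosts that drift below the
      physical window);
    * a small buffer of extra roots is tracked so degenerate shells at the
      requested cutoff cannot shed members; and
    * (near-)degenerate clusters are treated blockwise - an orthonormal
      cluster basis X with block matrix B = X^T A X and block residual
      A X - X B - so convergence is invariant to the arbitrary mixing of
      eigenvectors inside a cluster.

    With CVS, vectors are stored compressed on the core occupied rows.
    """
    if spin not in ("both", "singlet"):
        raise ValueError("spin must be 'both' or 'singlet'")
    space = (
        _CVSCompressedSpace(op, side, spin) if op.cvs is not None
        else _FullVectorSpace(op, side, spin)
    )
    no, nv = op.shape1
    d1, d2 = space.denominators()

    # allowed singles window (core rows x virtuals under CVS)
    H = op.H
    if op.cvs is not None:
        occ_idx = space.core
    else:
        occ_idx = np.arange(no)
    n_sing = len(occ_idx) * nv
    if n_sing == 0:
        raise DavidsonError("no allowed guess space (empty CVS window?)", [])
    n_eff = n_sing // 4 if spin == "singlet" else n_sing
    n_track = min(n_roots + 2, n_eff)
    if n_track < n_roots:
        raise DavidsonError(
            f"CVS singles window supports only {n_eff} roots", []
        )
    if max_space is None:
        max_space = max(12 * n_track, 48)

    # guesses: eigenvectors of the singles-singles (CIS-like) block
    rows = np.repeat(occ_idx, nv)
    cols = np.tile(np.arange(nv), len(occ_idx))
    Acis = (
        H.f_vv[np.ix_(cols, cols)] * (rows[:, None] == rows[None, :])
        - H.f_oo[np.ix_(rows, rows)].T * (cols[:, None] == cols[None, :])
        - H.ovov[rows[None, :], cols[:, None], rows[:, None], cols[None, :]]
    )
    if spin == "singlet":
        # spin-adapted guesses: symmetric alpha/beta combinations over
        # spatial (occupied, virtual) pairs
        pairs = [
            (p, q)
            for p in range(n_sing)
            for q in range(p + 1, n_sing)
            if rows[p] % 2 == 0 and rows[q] == rows[p] + 1
            and cols[p] % 2 == 0 and cols[q] == cols[p] + 1
        ]
        Bs = np.zeros((n_sing, len(pairs)))
        for k, (p, q) in enumerate(pairs):
            Bs[p, k] = Bs[q, k] = 1.0 / np.sqrt(2.0)
        As = Bs.T @ Acis @ Bs
        wc, Vs = np.linalg.eigh(0.5 * (As + As.T))
        Vc = Bs @ Vs
    else:
        wc, Vc = np.linalg.eigh(0.5 * (Acis + Acis.T))
    n_guess = min(n_track + 2, Vc.shape[1])
    basis = _orthonormalize(
        [space.singles_guess(Vc[:, k]) for k in range(n_guess)], space
    )
    sigmas = [space.apply(v) for v in basis]

    theta_old: np.ndarray | None = None
    prev_coefs: np.ndarray | None = None
    for it in range(max_iter):
        m = len(basis)
        M = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                M[i, j] = space.dot(basis[i], sigmas[j])
        w, V = scipy.linalg.eig(M)
        idx = np.argsort(w.real)
        real_ok = [k for k in idx if abs(w[k].imag) < 1e-6]
        if len(real_ok) < n_roots:
            real_ok = list(idx)
        if prev_coefs is None:
            sel = real_ok[:n_track]
        else:
            P = np.zeros((m, prev_coefs.shape[1]))
            P[: prev_coefs.shape[0], :] = prev_coefs
            Q, _ = np.linalg.qr(P)
            scores = []
            for k in real_ok:
                c = V[:, k].real
                nc_ = np.linalg.norm(c)
                scores.append(np.linalg.norm(Q.T @ c) / (nc_ + 1e-300))
            top = np.argsort(scores)[::-1][: min(n_track, len(real_ok))]
            sel = sorted((real_ok[k] for k in top), key=lambda k: w[k].real)

        # cluster the selected eigenvalues, build orthonormal cluster bases
        clusters: list[list[int]] = [[sel[0]]]
        for k in sel[1:]:
            if w[k].real - w[clusters[-1][-1]].real < cluster_tol:
                clusters[-1].append(k)
            else:
                clusters.append([k])

        theta_list: list[float] = []
        ritz: list = []
        residuals: list[float] = []
        resvecs: list = []
        shifts: list[float] = []
        coef_cols: list[np.ndarray] = []
        for cl in clusters:
            C = np.column_stack([V[:, k].real for k in cl])
            C, _ = np.linalg.qr(C)
            X, AX = [], []
            for col in range(C.shape[1]):
                c = C[:, col]
                x1 = sum(ci * b[0] for ci, b in zip(c, basis))
                x2 = sum(ci * b[1] for ci, b in zip(c, basis))
                a1 = sum(ci * s[0] for ci, s in zip(c, sigmas))
                a2 = sum(ci * s[1] for ci, s in zip(c, sigmas))
                X.append((x1, x2))
                AX.append((a1, a2))
            for i in range(len(X)):
                for j in range(i):
                    ov = space.dot(X[j], X[i])
                    X[i] = (X[i][0] - ov * X[j][0], X[i][1] - ov * X[j][1])
                    AX[i] = (AX[i][0] - ov * AX[j][0], AX[i][1] - ov * AX[j][1])
                nrm = space.norm(X[i])
                X[i] = (X[i][0] / nrm, X[i][1] / nrm)
                AX[i] = (AX[i][0] / nrm, AX[i][1] / nrm)
            B = np.array([[space.dot(xi, axj) for axj in AX] for xi in X])
            wB = np.linalg.eigvals(B)
            theta_list.extend(sorted(wB.real))
            for col in range(len(X)):
                r1c = AX[col][0] - sum(B[i, col] * X[i][0] for i in range(len(X)))
                r2c = AX[col][1] - sum(B[i, col] * X[i][1] for i in range(len(X)))
                ritz.append(X[col])
                resvecs.append((r1c, r2c))
                residuals.append(space.norm((r1c, r2c)))
                shifts.append(float(np.mean(wB.real)))
                coef_cols.append(C[:, col])
        theta = np.array(theta_list)
        prev_coefs = np.column_stack(coef_cols)

        if verbose:
            print(
                f"davidson[{side}] it={it} dim={m} "
                f"theta={np.round(theta, 6)} res={np.round(residuals, 5)}",
                flush=True,
            )
        if theta_old is None or len(theta_old) != len(theta):
            de = np.full(len(theta), np.inf)
        else:
            de = np.abs(np.sort(theta) - np.sort(theta_old))
        theta_old = theta.copy()
        conv = [
            residuals[k] < res_tol and de[k] < e_tol for k in range(len(theta))
        ]
        if len(theta) >= n_roots and all(conv[:n_roots]):
            return _finalize_states(theta, ritz, residuals, n_roots, space)

        if m + n_track > max_space:
            basis = _orthonormalize(ritz, space)
            sigmas = [space.apply(v) for v in basis]
            prev_coefs = np.eye(len(basis))[:, : len(ritz)]
            theta_old = None
            continue
        added = 0
        for k in range(len(theta)):
            if residuals[k] < 0.1 * res_tol:
                continue
            R = resvecs[k]
            den1 = shifts[k] - d1
            den2 = shifts[k] - d2
            den1 = np.where(np.abs(den1) < 1e-2, np.sign(den1 + 1e-12) * 1e-2, den1)
            den2 = np.where(np.abs(den2) < 1e-2, np.sign(den2 + 1e-12) * 1e-2, den2)
            corr = space.project((R[0] / den1, R[1] / den2))
            nrm0 = space.norm(corr)
            corr = _project_out(corr, basis, space)
            if space.norm(corr) < 1e-4 * nrm0:
                corr = _project_out(corr, basis, space)
            nrm = space.norm(corr)
            if nrm > 1e-9 * max(nrm0, 1.0):
                corr = (corr[0] / nrm, corr[1] / nrm)
                basis.append(corr)
                sigmas.append(space.apply(corr))
                added += 1
        if added == 0:
            if len(theta) >= n_roots and all(
                residuals[k] < res_tol for k in range(n_roots)
            ):
                return _finalize_states(theta, ritz, residuals, n_roots, space)
            raise DavidsonError(
                f"Davidson stagnated at iteration {it} "
                f"(residuals {np.array(residuals)})",
                _finalize_states(theta, ritz, residuals,
                                 min(n_roots, len(theta)), space),
            )
    raise DavidsonError(
        f"Davidson did not converge in {max_iter} iterations",
        [],
    )


def _finalize_states(theta, ritz, residuals, n_roots, space) -> list[EOMState]:
    order = np.argsort(theta)[:n_roots]
    out = []
    for k in order:
        full = space.unpack(ritz[k])
        out.append(
            EOMState(omega=float(theta[k]), r1=full[0], r2=full[1],
                     residual=residuals[k])
        )
    return out


def _orthonormalize(vecs, space=None):
    dot = cc_dot if space is None else space.dot
    out = []
    for v in vecs:
        nrm0 = float(np.sqrt(dot(v, v)))
        v = _project_out(v, out, space)
        nrm = float(np.sqrt(dot(v, v)))
        if nrm > 1e-8 * max(nrm0, 1.0):
            out.append((v[0] / nrm, v[1] / nrm))
    return out


def _project_out(v, basis, space=None):
    # two Gram-Schmidt passes: a single pass loses orthogonality badly when
    # the preconditioned corrections are nearly dependent, and the oblique
    # subspace matrix then grows spurious eigenvalues
    dot = cc_dot if space is None else space.dot
    r1, r2 = v[0].copy(), v[1].copy()
    for _ in range(2):
        for b in basis:
            c = dot(b, (r1, r2))
            r1 -= c * b[0]
            r2 -= c * b[1]
    return (r1, r2)


# ---------------------------------------------------------------------------
# biorthonormalization
# ---------------------------------------------------------------------------


def biorthonormalize(
    lefts: list[EOMState],
    rights: list[EOMState],
    l0: GroundStateLambda,
    degeneracy_tol: float = 1e-6,
) -> list[EOMState]:
    """Pair left/right eigenvectors, rescale to L^k . R^l = delta_kl, and
    attach r0 = -l0 . r_k; returns the right states with left vectors set."""
    if len(lefts) != len(rights):
        raise ValueError("left/right state counts differ")
    for L, R in zip(lefts, rights):
        if abs(L.omega - R.omega) > 1e-6:
            raise ValueError(
                f"left/right eigenvalues disagree: {L.omega} vs {R.omega}"
            )
    # group (near-)degenerate blocks by right eigenvalue
    n = len(rights)
    used = np.zeros(n, bool)
    out: list[EOMState] = []
    k = 0
    while k < n:
        block = [k]
        while (
            block[-1] + 1 < n
            and abs(rights[block[-1] + 1].omega - rights[k].omega) < degeneracy_tol
        ):
            block.append(block[-1] + 1)
        O = np.array([
            [cc_dot((lefts[i].r1, lefts[i].r2), (rights[j].r1, rights[j].r2))
             for j in block]
            for i in block
        ])
        try:
            Oinv = np.linalg.inv(O)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "singular left/right pairing within a degenerate block; "
                "tighten the eigensolver tolerances"
            ) from exc
        for col, j in enumerate(block):
            st = rights[j]
            lt1 = sum(Oinv[col, row] * lefts[i].r1 for row, i in enumerate(block))
            lt2 = sum(Oinv[col, row] * lefts[i].r2 for row, i in enumerate(block))
            st.l1, st.l2 = lt1, lt2
            st.left_residual = lefts[j].residual
            st.r0 = -cc_dot((l0.l1, l0.l2), (st.r1, st.r2))
            st.biorthonormalized = True
            out.append(st)
        k = block[-1] + 1
    return out
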