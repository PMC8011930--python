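"""Brute-force determinant-space reference implementations.

This module exists to validate the production coupled-cluster code at tiny
system sizes. It provides:

* full configuration interaction (FCI) by dense diagonalization of the
  Hamiltonian in the complete determinant basis (Slater-Condon rules), with
  length-gauge oscillator strengths; and
* a determinant-space similarity transform: given converged cluster
  amplitudes, exp(-T) H exp(T) is formed as an explicit matrix, from which
  exact Jacobian / eta / transition-moment blocks are extracted for
  comparison against the einsum implementation.

Everything here scales factorially and is only meant for a handful of
electrons in a handful of orbitals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.linalg


def spin_orbital_integrals(h_mo: np.ndarray, g_mo: np.ndarray):
    """Interleaved spin-orbital one-body and antisymmetrized two-body
    integrals from spatial MO arrays (g in Mulliken (pq|rs) order)."""
    n = h_mo.shape[0]
    nso = 2 * n
    h_so = np.zeros((nso, nso))
    h_so[0::2, 0::2] = h_mo
    h_so[1::2, 1::2] = h_mo
    # <PQ|RS> = (pr|qs) delta(sP,sR) delta(sQ,sS)
    g_phys = np.zeros((nso, nso, nso, nso))
    for sp in (0, 1):
        for sq in (0, 1):
            g_phys[sp::2, sq::2, sp::2, sq::2] = g_mo.transpose(0, 2, 1, 3)
    g_anti = g_phys - g_phys.transpose(0, 1, 3, 2)
    return h_so, g_anti


def all_determinants(n_so: int, n_el: int) -> list[tuple[int, ...]]:
    return [tuple(c) for c in combinations(range(n_so), n_el)]


def _phase_and_diff(d1: tuple[int, ...], d2: tuple[int, ...]):
    """Spin orbitals unique to each determinant and the alignment sign."""
    s1, s2 = set(d1), set(d2)
    only1 = sorted(s1 - s2)
    only2 = sorted(s2 - s1)
    if len(only1) > 2:
        return only1, only2, 0.0
    # phase: move unique orbitals of each determinant to the front
    sign = 1.0
    for k, p in enumerate(only1):
        sign *= (-1.0) ** (d1.index(p) - k)
    for k, p in enumerate(only2):
        sign *= (-1.0) ** (d2.index(p) - k)
    return only1, only2, sign


def build_hamiltonian(
    dets: list[tuple[int, ...]], h_so: np.ndarray, g_anti: np.ndarray
) -> np.ndarray:
    """Dense Hamiltonian in the determinant basis via Slater-Condon rules."""
    nd = len(dets)
    H = np.zeros((nd, nd))
    for I in range(nd):
        dI = dets[I]
        for J in range(I + 1):
            dJ = dets[J]
            o1, o2, sign = _phase_and_diff(dI, dJ)
            if sign == 0.0:
                continue
            common = sorted(set(dI) & set(dJ))
            if len(o1) == 0:
                val = sum(h_so[p, p] for p in dI)
                val += 0.5 * sum(
                    g_anti[p, q, p, q] for p in dI for q in dI
                )
            elif len(o1) == 1:
                m, p = o1[0], o2[0]
                val = h_so[m, p] + sum(g_anti[m, n, p, n] for n in common)
                val *= sign
            else:
                (m, n), (p, q) = o1, o2
                val = sign * g_anti[m, n, p, q]
            H[I, J] = val
            H[J, I] = val
    return H


def build_one_body(
    dets: list[tuple[int, ...]], m_so: np.ndarray
) -> np.ndarray:
    """Dense one-body operator in the determinant basis."""
    nd = len(dets)
    M = np.zeros((nd, nd))
    for I in range(nd):
        dI = dets[I]
        for J in range(I + 1):
            dJ = dets[J]
            o1, o2, sign = _phase_and_diff(dI, dJ)
            if sign == 0.0 or len(o1) > 1:
                continue
            if len(o1) == 0:
                val = sum(m_so[p, p] for p in dI)
            else:
                val = sign * m_so[o1[0], o2[0]]
            M[I, J] = val
            M[J, I] = val
    return M


def apply_string(det: tuple[int, ...], ann: list[int], cre: list[int]):
    """Apply annihilators (right to left) then creators to a determinant.

    Returns (new_det, phase) or (None, 0) if the result vanishes.
    """
    occ = list(det)
    phase = 1.0
    for p in reversed(ann):
        if p not in occ:
            return None, 0.0
        idx = occ.index(p)
        phase *= (-1.0) ** idx
        occ.pop(idx)
    for p in reversed(cre):
        if p in occ:
            return None, 0.0
        idx = int(np.searchsorted(occ, p))
        phase *= (-1.0) ** idx
        occ.insert(idx, p)
    return tuple(occ), phase


class DeterminantSpace:
    """Complete determinant basis plus amplitude-space bookkeeping.

    Spin orbitals are interleaved (2p = alpha, 2p+1 = beta of spatial p) and
    the reference occupies the first ``n_el`` spin orbitals. Amplitude-space
    basis states follow tau_mu|HF> phase conventions: singles a+_a a_i|HF>,
    doubles a+_a a+_b a_j a_i |HF> for i<j, a<b (indices counted within the
    occupied / virtual lists).
    """

    def __init__(self, n_so: int, n_el: int):
        self.n_so = n_so
        self.n_el = n_el
        self.dets = all_determinants(n_so, n_el)
        self.index = {d: k for k, d in enumerate(self.dets)}
        self.occ = list(range(n_el))
        self.virt = list(range(n_el, n_so))
        self.ref = tuple(self.occ)
        self.nocc = len(self.occ)
        self.nvirt = len(self.virt)
        self.singles = [(i, a) for i in range(self.nocc) for a in range(self.nvirt)]
        self.doubles = [
            (i, j, a, b)
            for i in range(self.nocc) for j in range(i + 1, self.nocc)
            for a in range(self.nvirt) for b in range(a + 1, self.nvirt)
        ]

    # -- amplitude-space basis vectors in the determinant basis ------------
    def basis_matrix(self) -> np.ndarray:
        """Columns: |HF>, tau_mu|HF> for singles then doubles."""
        nd = len(self.dets)
        cols = [self._unit(self.ref, 1.0)]
        for (i, a) in self.singles:
            d, ph = apply_string(self.ref, [self.occ[i]], [self.virt[a]])
            cols.append(self._unit(d, ph))
        for (i, j, a, b) in self.doubles:
            d, ph = apply_string(
                self.ref, [self.occ[j], self.occ[i]], [self.virt[a], self.virt[b]]
            )
            cols.append(self._unit(d, ph))
        return np.array(cols).T

    def _unit(self, det, phase):
        v = np.zeros(len(self.dets))
        if det is not None:
            v[self.index[det]] = phase
        return v

    # -- cluster operator as a determinant-space matrix --------------------
    def cluster_matrix(self, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """T = sum t1_ia a+_a a_i + 1/4 sum t2_ijab a+_a a+_b a_j a_i."""
        nd = len(self.dets)
        T = np.zeros((nd, nd))
        for k, det in enumerate(self.dets):
            for i, io in enumerate(self.occ):
                for a, av in enumerate(self.virt):
                    if t1[i, a] == 0.0:
                        continue
                    d, ph = apply_string(det, [io], [av])
                    if d is not None:
                        T[self.index[d], k] += ph * t1[i, a]
            for i, io in enumerate(self.occ):
                for j, jo in enumerate(self.occ):
                    for a, av in enumerate(self.virt):
                        for b, bv in enumerate(self.virt):
                            amp = t2[i, j, a, b]
                            if amp == 0.0:
                                continue
                            d, ph = apply_string(det, [jo, io], [av, bv])
                            if d is not None:
                                T[self.index[d], k] += 0.25 * ph * amp
        return T

    def similarity_transform(self, M: np.ndarray, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """exp(-T) M exp(T) in the determinant basis (T is nilpotent)."""
        T = self.cluster_matrix(t1, t2)
        eT = scipy.linalg.expm(T)
        emT = scipy.linalg.expm(-T)
        return emT @ M @ eT

    def amplitude_blocks(self, Mbar: np.ndarray):
        """Project a determinant-space operator onto {|HF>, singles, doubles}.

        Returns (scalar M00, row eta over amplitudes, column xi over
        amplitudes, amplitude-block matrix), all in tau_mu ordering.
        """
        B = self.basis_matrix()
        P = B.T @ Mbar @ B
        return P[0, 0], P[0, 1:], P[1:, 0], P[1:, 1:]


def fci_states(h_so, g_anti, n_el, n_so, e_nuc=0.0):
    """All FCI eigenstates: (energies, vectors, dets)."""
    dets = all_determinants(n_so, n_el)
    H = build_hamiltonian(dets, h_so, g_anti)
    w, V = np.linalg.eigh(H)
    return w + e_nuc, V, dets


def fci_oscillator_strengths(
    h_so, g_anti, m_so_xyz, n_el, n_so, n_states: int
):
    """FCI excitation energies (Hartree) and length-gauge oscillator
    strengths out of the ground state, for singlet-accessible states.

    ``m_so_xyz`` are the three spin-orbital position-operator matrices.
    States with zero transition moment (e.g. triplets) are included with
    f = 0; the caller filters as needed.
    """
    dets = all_determinants(n_so, n_el)
    H = build_hamiltonian(dets, h_so, g_anti)
    w, V = np.linalg.eigh(H)
    mmats = [build_one_body(dets, m) for m in m_so_xyz]
    omegas = w[1 : n_states + 1] - w[0]
    fs = []
    for k in range(1, n_states + 1):
        t2sum = sum((V[:, 0] @ M @ V[:, k]) ** 2 for M in mmats)
        fs.append(2.0 / 3.0 * omegas[k - 1] * t2sum)
    return omegas, np.array(fs)
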