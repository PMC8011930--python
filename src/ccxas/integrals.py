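"""AO integrals over contracted cartesian Gaussians (McMurchie-Davidson).

Overlap, kinetic, nuclear attraction, dipole and two-electron repulsion
integrals are evaluated with Hermite Gaussian expansions; the hot loops are
numba-compiled. The two-electron integrals are returned as a full (pq|rs)
array in the Mulliken convention, adequate for the desk-scale bases this
package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .basis import Shell, cartesian_components
from .molecule import Molecule


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _boys(m_max, x, out):
    """Boys function F_m(x) for m = 0..m_max into ``out``."""
    if x < 1e-13:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if x < 35.0:
        # series for F_{m_max}, then stable downward recursion
        ex = np.exp(-x)
        term = 1.0 / (2 * m_max + 1)
        total = term
        k = 1
        while True:
            term *= 2.0 * x / (2 * m_max + 2 * k + 1)
            total += term
            if term < 1e-17 * total or k > 500:
                break
            k += 1
        out[m_max] = ex * total
        for m in range(m_max, 0, -1):
            out[m - 1] = (2.0 * x * out[m] + ex) / (2 * m - 1)
    else:
        ex = np.exp(-x)
        out[0] = 0.5 * np.sqrt(np.pi / x)
        for m in range(m_max):
            out[m + 1] = ((2 * m + 1) * out[m] - ex) / (2.0 * x)


@njit(cache=True)
def _hermite_e(imax, jmax, a, b, ab_dist):
    """Hermite expansion coefficients E_t^{ij} along one dimension.

    Returns E with shape (imax+1, jmax+1, imax+jmax+1).
    """
    p = a + b
    mu = a * b / p
    E = np.zeros((imax + 1, jmax + 1, imax + jmax + 2))
    E[0, 0, 0] = np.exp(-mu * ab_dist * ab_dist)
    xpa = -b * ab_dist / p  # P - A with A - B = ab_dist
    xpb = a * ab_dist / p   # P - B
    for i in range(imax + 1):
        for j in range(jmax + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                for t in range(i + j + 1):
                    v = xpa * E[i - 1, 0, t]
                    if t > 0:
                        v += E[i - 1, 0, t - 1] / (2 * p)
                    v += (t + 1) * E[i - 1, 0, t + 1]
                    E[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = xpb * E[i, j - 1, t]
                    if t > 0:
                        v += E[i, j - 1, t - 1] / (2 * p)
                    v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v
    return E


@njit(cache=True)
def _hermite_r(L, alpha, X, Y, Z):
    """Auxiliary Hermite integrals R_{tuv} for t+u+v <= L."""
    T = alpha * (X * X + Y * Y + Z * Z)
    F = np.zeros(L + 1)
    _boys(L, T, F)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))  # [n, t, u, v]
    for n in range(L + 1):
        R[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for order in range(1, L + 1):
        for n in range(L - order + 1):
            for t in range(order + 1):
                for u in range(order - t + 1):
                    v = order - t - u
                    if t > 0:
                        val = X * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


@njit(cache=True)
def _one_electron_kernels(
    sh_l, sh_off, sh_nprim, sh_poff, sh_center, sh_atom,
    pr_exp, pr_coef, comps_flat, comps_off,
    charges, coords, origin, n_ao,
):
    """Overlap, kinetic, nuclear attraction and dipole AO matrices."""
    n_sh = len(sh_l)
    S = np.zeros((n_ao, n_ao))
    T = np.zeros((n_ao, n_ao))
    V = np.zeros((n_ao, n_ao))
    D = np.zeros((3, n_ao, n_ao))
    for ish in range(n_sh):
        la = sh_l[ish]
        ca = sh_center[ish]
        na = (la + 1) * (la + 2) // 2
        for jsh in range(ish + 1):
            lb = sh_l[jsh]
            cb = sh_center[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            L = la + lb
            for pa in range(sh_nprim[ish]):
                a = pr_exp[sh_poff[ish] + pa]
                da = pr_coef[sh_poff[ish] + pa]
                for pb in range(sh_nprim[jsh]):
                    b = pr_exp[sh_poff[jsh] + pb]
                    db = pr_coef[sh_poff[jsh] + pb]
                    p = a + b
                    cc = da * db
                    pref = cc * (np.pi / p) ** 1.5
                    # E tables per dimension, angular momenta extended for
                    # kinetic (j+2) and dipole (i+1)
                    Ex = _hermite_e(la + 1, lb + 2, a, b, ca[0] - cb[0])
                    Ey = _hermite_e(la + 1, lb + 2, a, b, ca[1] - cb[1])
                    Ez = _hermite_e(la + 1, lb + 2, a, b, ca[2] - cb[2])
                    P = (a * ca + b * cb) / p
                    # nuclear attraction Hermite table per center below
                    for ia in range(na):
                        ax = comps_flat[3 * (comps_off[la] + ia)]
                        ay = comps_flat[3 * (comps_off[la] + ia) + 1]
                        az = comps_flat[3 * (comps_off[la] + ia) + 2]
                        for ib in range(nb):
                            bx = comps_flat[3 * (comps_off[lb] + ib)]
                            by = comps_flat[3 * (comps_off[lb] + ib) + 1]
                            bz = comps_flat[3 * (comps_off[lb] + ib) + 2]
                            sx = Ex[ax, bx, 0]
                            sy = Ey[ay, by, 0]
                            sz = Ez[az, bz, 0]
                            sval = pref * sx * sy * sz
                            # kinetic 1D pieces
                            kx = -2.0 * b * b * Ex[ax, bx + 2, 0] \
                                + b * (2 * bx + 1) * Ex[ax, bx, 0]
                            if bx > 1:
                                kx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                            ky = -2.0 * b * b * Ey[ay, by + 2, 0] \
                                + b * (2 * by + 1) * Ey[ay, by, 0]
                            if by > 1:
                                ky -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                            kz = -2.0 * b * b * Ez[az, bz + 2, 0] \
                                + b * (2 * bz + 1) * Ez[az, bz, 0]
                            if bz > 1:
                                kz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                            tval = pref * (kx * sy * sz + sx * ky * sz + sx * sy * kz)
                            # dipole (about origin): <a|(x-ox)|b> etc.
                            dxv = Ex[ax + 1, bx, 0] + (ca[0] - origin[0]) * Ex[ax, bx, 0]
                            dyv = Ey[ay + 1, by, 0] + (ca[1] - origin[1]) * Ey[ay, by, 0]
                            dzv = Ez[az + 1, bz, 0] + (ca[2] - origin[2]) * Ez[az, bz, 0]
                            mu_x = pref * dxv * sy * sz
                            mu_y = pref * sx * dyv * sz
                            mu_z = pref * sx * sy * dzv
                            i_ao = sh_off[ish] + ia
                            j_ao = sh_off[jsh] + ib
                            S[i_ao, j_ao] += sval
                            T[i_ao, j_ao] += tval
                            D[0, i_ao, j_ao] += mu_x
                            D[1, i_ao, j_ao] += mu_y
                            D[2, i_ao, j_ao] += mu_z
                    # nuclear attraction over all centers
                    for ic in range(len(charges)):
                        Rt = _hermite_r(
                            L, p,
                            P[0] - coords[ic, 0],
                            P[1] - coords[ic, 1],
                            P[2] - coords[ic, 2],
                        )
                        zfac = -charges[ic] * cc * 2.0 * np.pi / p
                        for ia in range(na):
                            ax = comps_flat[3 * (comps_off[la] + ia)]
                            ay = comps_flat[3 * (comps_off[la] + ia) + 1]
                            az = comps_flat[3 * (comps_off[la] + ia) + 2]
                            for ib in range(nb):
                                bx = comps_flat[3 * (comps_off[lb] + ib)]
                                by = comps_flat[3 * (comps_off[lb] + ib) + 1]
                                bz = comps_flat[3 * (comps_off[lb] + ib) + 2]
                                acc = 0.0
                                for t in range(ax + bx + 1):
                                    et = Ex[ax, bx, t]
                                    if et == 0.0:
                                        continue
                                    for u in range(ay + by + 1):
                                        eu = Ey[ay, by, u]
                                        if eu == 0.0:
                                            continue
                                        for v in range(az + bz + 1):
                                            ev = Ez[az, bz, v]
                                            if ev == 0.0:
                                                continue
                                            acc += et * eu * ev * Rt[t, u, v]
                                V[sh_off[ish] + ia, sh_off[jsh] + ib] += zfac * acc
    # symmetrize
    for i in range(n_ao):
        for j in range(i):
            S[j, i] = S[i, j]
            T[j, i] = T[i, j]
            V[j, i] = V[i, j]
            for d in range(3):
                D[d, j, i] = D[d, i, j]
    return S, T, V, D


@njit(cache=True)
def _eri_kernel(
    sh_l, sh_off, sh_nprim, sh_poff, sh_center,
    pr_exp, pr_coef, comps_flat, comps_off, n_ao,
):
    """Full (pq|rs) Mulliken-convention ERI array with 8-fold symmetry."""
    n_sh = len(sh_l)
    g = np.zeros((n_ao, n_ao, n_ao, n_ao))
    for ish in range(n_sh):
        la = sh_l[ish]
        ca = sh_center[ish]
        na = (la + 1) * (la + 2) // 2
        for jsh in range(ish + 1):
            lb = sh_l[jsh]
            cb = sh_center[jsh]
            nb = (lb + 1) * (lb + 2) // 2
            for ksh in range(ish + 1):
                lc = sh_l[ksh]
                cc_ = sh_center[ksh]
                nc = (lc + 1) * (lc + 2) // 2
                lsh_max = jsh if ksh == ish else ksh
                for lsh in range(lsh_max + 1):
                    ld = sh_l[lsh]
                    cd = sh_center[lsh]
                    nd = (ld + 1) * (ld + 2) // 2
                    Lab = la + lb
                    Lcd = lc + ld
                    L = Lab + Lcd
                    block = np.zeros((na, nb, nc, nd))
                    for pa in range(sh_nprim[ish]):
                        a = pr_exp[sh_poff[ish] + pa]
                        da = pr_coef[sh_poff[ish] + pa]
                        for pb in range(sh_nprim[jsh]):
                            b = pr_exp[sh_poff[jsh] + pb]
                            db = pr_coef[sh_poff[jsh] + pb]
                            p = a + b
                            P = (a * ca + b * cb) / p
                            Exab = _hermite_e(la, lb, a, b, ca[0] - cb[0])
                            Eyab = _hermite_e(la, lb, a, b, ca[1] - cb[1])
                            Ezab = _hermite_e(la, lb, a, b, ca[2] - cb[2])
                            for pc in range(sh_nprim[ksh]):
                                c = pr_exp[sh_poff[ksh] + pc]
                                dc = pr_coef[sh_poff[ksh] + pc]
                                for pd in range(sh_nprim[lsh]):
                                    d = pr_exp[sh_poff[lsh] + pd]
                                    dd = pr_coef[sh_poff[lsh] + pd]
                                    q = c + d
                                    Q = (c * cc_ + d * cd) / q
                                    alpha = p * q / (p + q)
                                    Excd = _hermite_e(lc, ld, c, d, cc_[0] - cd[0])
                                    Eycd = _hermite_e(lc, ld, c, d, cc_[1] - cd[1])
                                    Ezcd = _hermite_e(lc, ld, c, d, cc_[2] - cd[2])
                                    Rt = _hermite_r(
                                        L, alpha,
                                        P[0] - Q[0], P[1] - Q[1], P[2] - Q[2],
                                    )
                                    pref = (
                                        da * db * dc * dd
                                        * 2.0 * np.pi ** 2.5
                                        / (p * q * np.sqrt(p + q))
                                    )
                                    for ia in range(na):
                                        ax = comps_flat[3 * (comps_off[la] + ia)]
                                        ay = comps_flat[3 * (comps_off[la] + ia) + 1]
                                        az = comps_flat[3 * (comps_off[la] + ia) + 2]
                                        for ib in range(nb):
                                            bx = comps_flat[3 * (comps_off[lb] + ib)]
                                            by = comps_flat[3 * (comps_off[lb] + ib) + 1]
                                            bz = comps_flat[3 * (comps_off[lb] + ib) + 2]
                                            for ic in range(nc):
                                                cx = comps_flat[3 * (comps_off[lc] + ic)]
                                                cy = comps_flat[3 * (comps_off[lc] + ic) + 1]
                                                cz = comps_flat[3 * (comps_off[lc] + ic) + 2]
                                                for id_ in range(nd):
                                                    dx = comps_flat[3 * (comps_off[ld] + id_)]
                                                    dy = comps_flat[3 * (comps_off[ld] + id_) + 1]
                                                    dz = comps_flat[3 * (comps_off[ld] + id_) + 2]
                                                    acc = 0.0
                                                    for t in range(ax + bx + 1):
                                                        et = Exab[ax, bx, t]
                                                        if et == 0.0:
                                                            continue
                                                        for u in range(ay + by + 1):
                                                            eu = Eyab[ay, by, u]
                                                            if eu == 0.0:
                                                                continue
                                                            for v in range(az + bz + 1):
                                                                ev = Ezab[az, bz, v]
                                                                if ev == 0.0:
                                                                    continue
                                                                etuv = et * eu * ev
                                                                for tt in range(cx + dx + 1):
                                                                    ft = Excd[cx, dx, tt]
                                                                    if ft == 0.0:
                                                                        continue
                                                                    for uu in range(cy + dy + 1):
                                                                        fu = Eycd[cy, dy, uu]
                                                                        if fu == 0.0:
                                                                            continue
                                                                        for vv in range(cz + dz + 1):
                                                                            fv = Ezcd[cz, dz, vv]
                                                                            if fv == 0.0:
                                                                                continue
                                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                                            acc += (
                                                                                etuv * ft * fu * fv * sgn
                                                                                * Rt[t + tt, u + uu, v + vv]
                                                                            )
                                                    block[ia, ib, ic, id_] += pref * acc
                    # scatter with 8-fold permutational symmetry
                    for ia in range(na):
                        for ib in range(nb):
                            for ic in range(nc):
                                for id_ in range(nd):
                                    val = block[ia, ib, ic, id_]
                                    i = sh_off[ish] + ia
                                    j = sh_off[jsh] + ib
                                    k = sh_off[ksh] + ic
                                    l = sh_off[lsh] + id_
                                    g[i, j, k, l] = val
                                    g[j, i, k, l] = val
                                    g[i, j, l, k] = val
                                    g[j, i, l, k] = val
                                    g[k, l, i, j] = val
                                    g[l, k, i, j] = val
                                    g[k, l, j, i] = val
                                    g[l, k, j, i] = val
    return g


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class AOIntegralSet:
    """AO-basis integrals: overlap, core Hamiltonian, ERIs, dipoles.

    ``g`` holds (pq|rs) in the Mulliken convention. ``dipole`` is the
    electronic position-operator matrix about ``origin`` (Bohr); the physical
    dipole operator is its negative plus the nuclear term, but only relative
    signs that cancel in oscillator strengths differ.
    """

    n_ao: int
    S: np.ndarray
    h: np.ndarray
    g: np.ndarray
    dipole: np.ndarray  # (3, n_ao, n_ao)
    e_nuc: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cholesky: np.ndarray | None = None  # optional (n_vec, n_ao, n_ao) factors


def _pack_shells(shells: list[Shell]):
    n_sh = len(shells)
    sh_l = np.array([s.l for s in shells], dtype=np.int64)
    sh_nprim = np.array([len(s.exps) for s in shells], dtype=np.int64)
    sh_poff = np.zeros(n_sh, dtype=np.int64)
    sh_off = np.zeros(n_sh, dtype=np.int64)
    off_p = 0
    off_ao = 0
    for i, s in enumerate(shells):
        sh_poff[i] = off_p
        sh_off[i] = off_ao
        off_p += len(s.exps)
        off_ao += s.n_functions
    pr_exp = np.concatenate([s.exps for s in shells])
    pr_coef = np.concatenate([s.coefs for s in shells])
    sh_center = np.array([s.center for s in shells])
    sh_atom = np.array([s.atom_index for s in shells], dtype=np.int64)
    lmax = int(sh_l.max())
    comps: list[tuple[int, int, int]] = []
    comps_off = np.zeros(lmax + 2, dtype=np.int64)
    for l in range(lmax + 1):
        comps_off[l] = len(comps)
        comps.extend(cartesian_components(l))
    comps_off[lmax + 1] = len(comps)
    comps_flat = np.array(comps, dtype=np.int64).ravel()
    return (sh_l, sh_off, sh_nprim, sh_poff, sh_center, sh_atom,
            pr_exp, pr_coef, comps_flat, comps_off, off_ao)


def compute_ao_integrals(
    molecule: Molecule,
    shells: list[Shell],
    origin: np.ndarray | None = None,
) -> AOIntegralSet:
    """Evaluate all AO integrals. Dipole origin defaults to the center of
    nuclear charge."""
    (sh_l, sh_off, sh_nprim, sh_poff, sh_center, sh_atom,
     pr_exp, pr_coef, comps_flat, comps_off, n_ao) = _pack_shells(shells)
    if origin is None:
        origin = molecule.center_of_nuclear_charge()
    origin = np.asarray(origin, dtype=float)
    charges = molecule.atomic_numbers.astype(np.float64)
    coords = molecule.coords_bohr
    S, T, V, D = _one_electron_kernels(
        sh_l, sh_off, sh_nprim, sh_poff, sh_center, sh_atom,
        pr_exp, pr_coef, comps_flat, comps_off,
        charges, coords, origin, n_ao,
    )
    g = _eri_kernel(
        sh_l, sh_off, sh_nprim, sh_poff, sh_center,
        pr_exp, pr_coef, comps_flat, comps_off, n_ao,
    )
    return AOIntegralSet(
        n_ao=n_ao, S=S, h=T + V, g=g, dipole=D,
        e_nuc=molecule.nuclear_repulsion(), origin=origin,
    )


def cholesky_decompose_eri(g: np.ndarray, threshold: float = 1e-8) -> np.ndarray:
    """Pivoted Cholesky factors of the ERI matrix G_{pq,rs} = (pq|rs).

    Returns L with shape (n_vec, n, n) such that the largest diagonal of the
    residual (pq|rs) - sum_J L^J_pq L^J_rs is below ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = g.shape[0]
    G = g.reshape(n * n, n * n).copy()
    diag = np.diag(G).copy()
    if diag.min() < -1e-10:
        raise np.linalg.LinAlgError(
            "ERI matrix is not positive semidefinite within tolerance"
        )
    vecs = []
    for _ in range(n * n):
        p = int(np.argmax(diag))
        dmax = diag[p]
        if dmax <= threshold:
            break
        col = G[:, p].copy()
        for L in vecs:
            col -= L * L[p]
        L = col / np.sqrt(max(dmax, 0.0))
        vecs.append(L)
        diag -= L * L
        diag = np.maximum(diag, 0.0)
    if not vecs:
        return np.zeros((0, n, n))
    return np.array(vecs).reshape(len(vecs), n, n)
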