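"""MO transformation and spin-orbital integral blocks.

The coupled-cluster modules work in an interleaved spin-orbital basis
(2p = alpha, 2p+1 = beta of spatial orbital p) built over a closed-shell
reference, with spatial orbitals ordered occupied-first. Antisymmetrized
physicists' integrals <pq||rs> are stored blockwise (oooo, ooov, oovv, ovov,
ovvv, vvvv); every other block follows from permutational symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def mo_transform(g_ao: np.ndarray, C: np.ndarray) -> np.ndarray:
    """AO (pq|rs) -> MO (pq|rs), Mulliken convention throughout."""
    g = np.einsum("pqrs,pi->iqrs", g_ao, C, optimize=True)
    g = np.einsum("iqrs,qj->ijrs", g, C, optimize=True)
    g = np.einsum("ijrs,rk->ijks", g, C, optimize=True)
    g = np.einsum("ijks,sl->ijkl", g, C, optimize=True)
    return g


def _so_maps(n_occ: int, n_virt: int):
    """Spatial index and spin arrays for the interleaved occ / virt SO lists."""
    occ_sp = np.repeat(np.arange(n_occ), 2)
    occ_spin = np.tile([0, 1], n_occ)
    virt_sp = np.repeat(np.arange(n_occ, n_occ + n_virt), 2)
    virt_spin = np.tile([0, 1], n_virt)
    return (occ_sp, occ_spin), (virt_sp, virt_spin)


def _antisym_block(g_mo, idx1, idx2, idx3, idx4):
    """<PQ||RS> for SO index lists idx = (spatial array, spin array)."""
    (p1, s1), (p2, s2), (p3, s3), (p4, s4) = idx1, idx2, idx3, idx4
    d13 = (s1[:, None] == s3[None, :]).astype(float)
    d24 = (s2[:, None] == s4[None, :]).astype(float)
    d14 = (s1[:, None] == s4[None, :]).astype(float)
    d23 = (s2[:, None] == s3[None, :]).astype(float)
    direct = g_mo[np.ix_(p1, p3, p2, p4)].transpose(0, 2, 1, 3)
    direct = direct * d13[:, None, :, None] * d24[None, :, None, :]
    exch = g_mo[np.ix_(p1, p4, p2, p3)].transpose(0, 2, 3, 1)
    exch = exch * d14[:, None, None, :] * d23[None, :, :, None]
    return direct - exch


def _one_body_so(m_mo, idx1, idx2):
    (p1, s1), (p2, s2) = idx1, idx2
    return m_mo[np.ix_(p1, p2)] * (s1[:, None] == s2[None, :])


@dataclass
class SpinOrbitalHamiltonian:
    """Fock and antisymmetrized two-electron blocks in the spin-orbital basis.

    ``e_ref`` is the energy of the reference determinant (including nuclear
    repulsion and, for reduced-space calculations, the contribution of the
    inactive occupied orbitals) so total energies are always comparable to
    full-space results.
    """

    nocc: int
    nvirt: int
    f_oo: np.ndarray
    f_ov: np.ndarray
    f_vv: np.ndarray
    oooo: np.ndarray
    ooov: np.ndarray
    oovv: np.ndarray
    ovov: np.ndarray  # <mb||je>
    ovvv: np.ndarray  # <ma||ef>
    vvvv: np.ndarray
    e_ref: float = 0.0
    dip_blocks: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def eps_occ(self) -> np.ndarray:
        return np.diag(self.f_oo)

    @property
    def eps_virt(self) -> np.ndarray:
        return np.diag(self.f_vv)

    @classmethod
    def from_spatial(
        cls,
        f_mo: np.ndarray,
        g_mo: np.ndarray,
        n_occ: int,
        e_ref: float = 0.0,
        dip_mo: np.ndarray | None = None,
    ) -> "SpinOrbitalHamiltonian":
        """Build all blocks from spatial MO arrays (occupied-first order)."""
        n_mo = f_mo.shape[0]
        n_virt = n_mo - n_occ
        o, v = _so_maps(n_occ, n_virt)
        dip_blocks = []
        if dip_mo is not None:
            for m in dip_mo:
                dip_blocks.append({
                    "oo": _one_body_so(m, o, o),
                    "ov": _one_body_so(m, o, v),
                    "vv": _one_body_so(m, v, v),
                })
        return cls(
            nocc=2 * n_occ,
            nvirt=2 * n_virt,
            f_oo=_one_body_so(f_mo, o, o),
            f_ov=_one_body_so(f_mo, o, v),
            f_vv=_one_body_so(f_mo, v, v),
            oooo=_antisym_block(g_mo, o, o, o, o),
            ooov=_antisym_block(g_mo, o, o, o, v),
            oovv=_antisym_block(g_mo, o, o, v, v),
            ovov=_antisym_block(g_mo, o, v, o, v),
            ovvv=_antisym_block(g_mo, o, v, v, v),
            vvvv=_antisym_block(g_mo, v, v, v, v),
            e_ref=e_ref,
            dip_blocks=dip_blocks,
        )

    def denominators(self):
        """Semicanonical orbital-energy denominators D_ia and D_ijab."""
        eo = self.eps_occ
        ev = self.eps_virt
        d1 = eo[:, None] - ev[None, :]
        d2 = (
            eo[:, None, None, None] + eo[None, :, None, None]
            - ev[None, None, :, None] - ev[None, None, None, :]
        )
        return d1, d2
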