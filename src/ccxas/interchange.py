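"""Engine-independent interchange of integrals and reference data.

A self-describing HDF5 container carries everything downstream modules need
(overlap, core Hamiltonian, ERIs or their Cholesky factors, dipoles, MO
coefficients, orbital energies, energies), so a calculation can be driven
from any integral/SCF engine that writes this layout. An FCIDUMP writer
(Molpro conventions) exports MO-basis integrals for third-party tools.
"""

from __future__ import annotations

import numpy as np

from .integrals import AOIntegralSet
from .scf import SCFResult

SCHEMA_VERSION = 1

_REQUIRED = ["S", "h", "mu_x", "mu_y", "mu_z", "C", "eps", "E_nuc", "E_hf", "n_occ"]


class InterchangeError(RuntimeError):
    pass


def dump_interchange(ints: AOIntegralSet, scf: SCFResult, path) -> None:
    """Write all fields losslessly (full float precision)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f["S"] = ints.S
        f["h"] = ints.h
        if ints.cholesky is not None:
            f["L_chol"] = ints.cholesky
        else:
            f["g"] = ints.g
        f["mu_x"], f["mu_y"], f["mu_z"] = ints.dipole
        f["origin"] = ints.origin
        f["C"] = scf.C
        f["eps"] = scf.eps
        f["E_nuc"] = ints.e_nuc
        f["E_hf"] = scf.e_hf
        f["n_occ"] = scf.n_occ


def load_interchange(path) -> tuple[AOIntegralSet, SCFResult]:
    import h5py

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise InterchangeError(
                f"schema version mismatch: file has {version}, expected {SCHEMA_VERSION}"
            )
        for name in _REQUIRED:
            if name not in f:
                raise InterchangeError(f"missing block {name!r} in interchange file")
        if "g" not in f and "L_chol" not in f:
            raise InterchangeError("missing block 'g' (or 'L_chol') in interchange file")
        S = f["S"][()]
        h = f["h"][()]
        chol = f["L_chol"][()] if "L_chol" in f else None
        if chol is not None:
            g = np.einsum("jpq,jrs->pqrs", chol, chol, optimize=True)
        else:
            g = f["g"][()]
        dipole = np.array([f["mu_x"][()], f["mu_y"][()], f["mu_z"][()]])
        origin = f["origin"][()] if "origin" in f else np.zeros(3)
        ints = AOIntegralSet(
            n_ao=S.shape[0], S=S, h=h, g=g, dipole=dipole,
            e_nuc=float(f["E_nuc"][()]), origin=origin, cholesky=chol,
        )
        scf = SCFResult(
            C=f["C"][()], eps=f["eps"][()], n_occ=int(f["n_occ"][()]),
            e_hf=float(f["E_hf"][()]), e_nuc=float(f["E_nuc"][()]),
            converged=True, n_iter=0,
        )
    return ints, scf


def write_fcidump(
    ints: AOIntegralSet, scf: SCFResult, path, tol: float = 1e-12
) -> None:
    """MO-basis FCIDUMP (Molpro conventions, 1-based indices, 8-fold
    permutational symmetry; core energy = nuclear repulsion)."""
    C = scf.C
    n = C.shape[1]
    h_mo = C.T @ ints.h @ C
    g_mo = np.einsum(
        "pqrs,pi,qj,rk,sl->ijkl", ints.g, C, C, C, C, optimize=True
    )
    n_elec = 2 * scf.n_occ
    with open(path, "w") as f:
        f.write(f"&FCI NORB={n},NELEC={n_elec},MS2=0,\n")
        f.write("  ORBSYM=" + "1," * n + "\n")
        f.write("  ISYM=1,\n&END\n")
        for p in range(n):
            for q in range(p + 1):
                for r in range(p + 1):
                    s_max = q if r == p else r
                    for s in range(s_max + 1):
                        v = g_mo[p, q, r, s]
                        if abs(v) > tol:
                            f.write(f"{v:23.16e} {p+1:4d} {q+1:4d} {r+1:4d} {s+1:4d}\n")
        for p in range(n):
            for q in range(p + 1):
                v = h_mo[p, q]
                if abs(v) > tol:
                    f.write(f"{v:23.16e} {p+1:4d} {q+1:4d}    0    0\n")
        f.write(f"{ints.e_nuc:23.16e}    0    0    0    0\n")


def read_fcidump(path):
    """Read back an FCIDUMP: (h_mo, g_mo, e_nuc, n_orb, n_elec)."""
    with open(path) as f:
        header = ""
        for line in f:
            header += line
            if "&END" in line or "/" in line.strip():
                break
        import re

        norb = int(re.search(r"NORB\s*=\s*(\d+)", header).group(1))
        nelec = int(re.search(r"NELEC\s*=\s*(\d+)", header).group(1))
        h = np.zeros((norb, norb))
        g = np.zeros((norb, norb, norb, norb))
        e_nuc = 0.0
        for line in f:
            parts = line.split()
            if len(parts) != 5:
                continue
            v = float(parts[0])
            p, q, r, s = (int(x) for x in parts[1:])
            if p == q == r == s == 0:
                e_nuc = v
            elif r == s == 0:
                h[p - 1, q - 1] = h[q - 1, p - 1] = v
            else:
                p, q, r, s = p - 1, q - 1, r - 1, s - 1
                for (a, b, c, d) in (
                    (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
                    (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
                ):
                    g[a, b, c, d] = v
    return h, g, e_nuc, norb, nelec
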