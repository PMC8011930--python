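"""Active/inactive orbital partitioning from Cholesky orbitals and PAOs.

Occupied orbitals: a pivoted Cholesky decomposition of the idempotent HF
density D, with pivots restricted to AOs on the active atoms, yields the
active occupied orbitals; the residual (inactive) density is then fully
decomposed for the inactive occupied set. Because D is idempotent with
respect to the overlap metric, the factors come out S-orthonormal.

Virtual orbitals: projected atomic orbitals (PAOs) — active-atom AO columns
with the occupied space projected out — orthonormalized by Lowdin canonical
orthonormalization; the inactive virtuals are the orthonormalized complement
of occupied + active virtual within the full AO span.

Finally the occupied-occupied and virtual-virtual Fock blocks are
semicanonicalized by separate rotations among active and among inactive
orbitals, which leaves the partition intact but gives diagonal within-block
Fock matrices (and hence well-defined orbital-energy denominators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import Shell, aos_on_atoms
from .molecule import Molecule


class PartitionInconsistencyError(RuntimeError):
    """Raised when block ranks do not add up to the expected counts."""


@dataclass
class ActiveAtomSelection:
    """Active atoms and the AOs centered on them."""

    atom_indices: list[int]
    ao_indices: np.ndarray

    @classmethod
    def from_atoms(cls, shells: list[Shell], atoms) -> "ActiveAtomSelection":
        atoms = sorted(int(a) for a in atoms)
        if not atoms:
            raise ValueError("active atom selection must be non-empty")
        n_atoms = max(s.atom_index for s in shells) + 1
        for a in atoms:
            if a < 0 or a >= n_atoms:
                raise ValueError(f"active atom index {a} outside 0..{n_atoms - 1}")
        return cls(atoms, aos_on_atoms(shells, atoms))


@dataclass
class OrbitalSpace:
    """Partitioned, semicanonical MO space over the AO basis.

    Column order inside each block is by ascending semicanonical energy.
    The full coefficient matrix (occupied blocks first, active before
    inactive) is S-orthonormal.
    """

    C_occ_act: np.ndarray
    C_occ_inact: np.ndarray
    C_virt_act: np.ndarray
    C_virt_inact: np.ndarray
    eps_occ_act: np.ndarray | None = None
    eps_occ_inact: np.ndarray | None = None
    eps_virt_act: np.ndarray | None = None
    eps_virt_inact: np.ndarray | None = None

    @property
    def n_occ_act(self) -> int:
        return self.C_occ_act.shape[1]

    @property
    def n_occ_inact(self) -> int:
        return self.C_occ_inact.shape[1]

    @property
    def n_virt_act(self) -> int:
        return self.C_virt_act.shape[1]

    @property
    def n_virt_inact(self) -> int:
        return self.C_virt_inact.shape[1]

    @property
    def n_occ(self) -> int:
        return self.n_occ_act + self.n_occ_inact

    @property
    def n_mo(self) -> int:
        return self.n_occ + self.n_virt_act + self.n_virt_inact

    @property
    def C_full(self) -> np.ndarray:
        """[occ_act | occ_inact | virt_act | virt_inact]."""
        return np.hstack([
            self.C_occ_act, self.C_occ_inact, self.C_virt_act, self.C_virt_inact
        ])

    @property
    def occ_active_flags(self) -> np.ndarray:
        return np.r_[
            np.ones(self.n_occ_act, bool), np.zeros(self.n_occ_inact, bool)
        ]

    @property
    def virt_active_flags(self) -> np.ndarray:
        return np.r_[
            np.ones(self.n_virt_act, bool), np.zeros(self.n_virt_inact, bool)
        ]


@dataclass
class PartitionReport:
    """Counts and diagnostics of one partitioning run."""

    n_occ_act: int
    n_occ_inact: int
    n_virt_act: int
    n_virt_inact: int
    occ_threshold: float
    pao_lindep_tol: float
    largest_neglected_active_diagonal: float
    pao_rank_deficit: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def __str__(self) -> str:
        return (
            "orbital partition:\n"
            f"  occupied  active/inactive: {self.n_occ_act}/{self.n_occ_inact}\n"
            f"  virtual   active/inactive: {self.n_virt_act}/{self.n_virt_inact}\n"
            f"  occupied Cholesky threshold: {self.occ_threshold:g} "
            f"(largest neglected active diagonal {self.largest_neglected_active_diagonal:.3e})\n"
            f"  PAO lindep tolerance: {self.pao_lindep_tol:g} "
            f"(rank deficit {self.pao_rank_deficit})"
        )


def cholesky_partition_occupied(
    D: np.ndarray,
    S: np.ndarray,
    sel: ActiveAtomSelection,
    threshold: float = 1e-2,
    rank_tol: float = 1e-8,
):
    """Restricted-pivot Cholesky split of the occupied density.

    Returns (C_occ_active, C_occ_inactive, largest neglected active
    diagonal). Pivots are restricted to active-atom AOs (largest diagonal
    first; ties by lowest AO index) until all active diagonals fall below
    ``threshold``; the residual density is then fully decomposed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = D.shape[0]
    n_occ = int(round(np.trace(D @ S)))
    R = D.copy()
    active = np.zeros(n, bool)
    active[sel.ao_indices] = True
    cols_act = []
    while True:
        diag = np.diag(R)
        d_act = np.where(active, diag, -np.inf)
        p = int(np.argmax(d_act))  # argmax returns the lowest index on ties
        if d_act[p] < threshold:
            largest_neglected = float(max(d_act[p], 0.0))
            break
        l = R[:, p] / np.sqrt(diag[p])
        cols_act.append(l)
        R = R - np.outer(l, l)
    cols_inact = []
    while True:
        diag = np.diag(R)
        p = int(np.argmax(diag))
        if diag[p] < rank_tol:
            break
        l = R[:, p] / np.sqrt(diag[p])
        cols_inact.append(l)
        R = R - np.outer(l, l)
    n_act, n_inact = len(cols_act), len(cols_inact)
    if n_act + n_inact != n_occ:
        raise PartitionInconsistencyError(
            f"occupied Cholesky ranks {n_act}+{n_inact} != n_occ {n_occ}; "
            "the decomposition threshold is inconsistent with an idempotent density"
        )
    C_act = np.array(cols_act).T if n_act else np.zeros((n, 0))
    C_inact = np.array(cols_inact).T if n_inact else np.zeros((n, 0))
    # refresh orthonormality within each block (spans are unchanged)
    if n_act:
        C_act = lowdin_canonical_orthonormalize(C_act, S, 1e-10)
    if n_inact:
        C_inact = lowdin_canonical_orthonormalize(C_inact, S, 1e-10)
    return C_act, C_inact, largest_neglected


def construct_active_paos(
    C_occ_all: np.ndarray, S: np.ndarray, sel: ActiveAtomSelection
) -> np.ndarray:
    """Raw (non-orthogonal) PAOs: (1 - D S) applied to active AO columns."""
    n = S.shape[0]
    if len(sel.ao_indices) == 0:
        return np.zeros((n, 0))
    D = C_occ_all @ C_occ_all.T
    P = np.eye(n) - D @ S
    return P[:, sel.ao_indices]


def lowdin_canonical_orthonormalize(
    C_raw: np.ndarray, S: np.ndarray, lindep_tol: float = 1e-6
) -> np.ndarray:
    """Lowdin canonical orthonormalization in the S metric.

    Keeps the metric eigenvectors with eigenvalue above ``lindep_tol``;
    the output O satisfies O^T S O = 1.
    """
    if lindep_tol <= 0:
        raise ValueError("lindep_tol must be positive")
    if C_raw.shape[1] == 0:
        return C_raw.copy()
    M = C_raw.T @ S @ C_raw
    w, U = np.linalg.eigh(M)
    keep = w > lindep_tol
    if not np.any(keep):
        warnings.warn("all metric eigenvalues below tolerance; empty orthonormal set",
                      stacklevel=2)
        return np.zeros((C_raw.shape[0], 0))
    return C_raw @ (U[:, keep] / np.sqrt(w[keep]))


def construct_inactive_virtuals(
    C_occ_all: np.ndarray,
    C_virt_active: np.ndarray,
    S: np.ndarray,
    n_mo: int,
    lindep_tol: float = 1e-6,
) -> np.ndarray:
    """Orthonormal complement of occupied + active virtual in the MO span."""
    n = S.shape[0]
    expected = n_mo - C_occ_all.shape[1] - C_virt_active.shape[1]
    if expected == 0:
        # active virtuals already span the whole virtual space
        return np.zeros((n, 0))
    Dsum = C_occ_all @ C_occ_all.T + C_virt_active @ C_virt_active.T
    P = np.eye(n) - Dsum @ S
    C = lowdin_canonical_orthonormalize(P, S, lindep_tol)
    if C.shape[1] != expected:
        raise PartitionInconsistencyError(
            f"inactive virtual rank {C.shape[1]} != expected {expected}; "
            "adjust the linear-dependence tolerance"
        )
    return C


def semicanonicalize(F_ao: np.ndarray, space: OrbitalSpace) -> OrbitalSpace:
    """Diagonalize the within-block Fock matrices by block-local rotations.

    Rotations never mix active with inactive nor occupied with virtual;
    each block is sorted by (energy, original index) so degeneracies are
    resolved deterministically.
    """
    def rotate(C):
        if C.shape[1] == 0:
            return C, np.zeros(0)
        f = C.T @ F_ao @ C
        w, U = np.linalg.eigh(f)
        order = np.lexsort((np.arange(len(w)), np.round(w, 12)))
        return C @ U[:, order], w[order]

    Coa, eoa = rotate(space.C_occ_act)
    Coi, eoi = rotate(space.C_occ_inact)
    Cva, eva = rotate(space.C_virt_act)
    Cvi, evi = rotate(space.C_virt_inact)
    return OrbitalSpace(
        C_occ_act=Coa, C_occ_inact=Coi, C_virt_act=Cva, C_virt_inact=Cvi,
        eps_occ_act=eoa, eps_occ_inact=eoi, eps_virt_act=eva, eps_virt_inact=evi,
    )


def partition_orbital_space(
    D: np.ndarray,
    S: np.ndarray,
    F_ao: np.ndarray,
    n_mo: int,
    sel: ActiveAtomSelection,
    occ_threshold: float = 1e-2,
    pao_lindep_tol: float = 1e-6,
) -> tuple[OrbitalSpace, PartitionReport]:
    """The full Cholesky/PAO pipeline: occupied split, active PAO virtuals,
    inactive virtual complement, semicanonicalization."""
    C_oa, C_oi, neglected = cholesky_partition_occupied(
        D, S, sel, threshold=occ_threshold
    )
    C_occ = np.hstack([C_oa, C_oi])
    pao_raw = construct_active_paos(C_occ, S, sel)
    C_va = lowdin_canonical_orthonormalize(pao_raw, S, pao_lindep_tol)
    # PAOs can at most span the virtual space
    n_virt = n_mo - C_occ.shape[1]
    if C_va.shape[1] > n_virt:
        raise PartitionInconsistencyError(
            f"active PAO rank {C_va.shape[1]} exceeds virtual dimension {n_virt}"
        )
    C_vi = construct_inactive_virtuals(C_occ, C_va, S, n_mo, pao_lindep_tol)
    space = OrbitalSpace(
        C_occ_act=C_oa, C_occ_inact=C_oi, C_virt_act=C_va, C_virt_inact=C_vi
    )
    space = semicanonicalize(F_ao, space)
    report = PartitionReport(
        n_occ_act=space.n_occ_act,
        n_occ_inact=space.n_occ_inact,
        n_virt_act=space.n_virt_act,
        n_virt_inact=space.n_virt_inact,
        occ_threshold=occ_threshold,
        pao_lindep_tol=pao_lindep_tol,
        largest_neglected_active_diagonal=neglected,
        pao_rank_deficit=pao_raw.shape[1] - C_va.shape[1],
    )
    return space, report


def full_active_space(C: np.ndarray, n_occ: int, eps: np.ndarray | None = None) -> OrbitalSpace:
    """Canonical orbitals wrapped as an all-active partition."""
    n_ao, n_mo = C.shape
    empty = np.zeros((n_ao, 0))
    return OrbitalSpace(
        C_occ_act=C[:, :n_occ], C_occ_inact=empty,
        C_virt_act=C[:, n_occ:], C_virt_inact=empty,
        eps_occ_act=None if eps is None else eps[:n_occ],
        eps_occ_inact=np.zeros(0),
        eps_virt_act=None if eps is None else eps[n_occ:],
        eps_virt_inact=np.zeros(0),
    )


def frozen_core_space(C: np.ndarray, n_occ: int, frozen_occ: list[int]) -> OrbitalSpace:
    """Canonical orbitals with chosen occupied orbitals marked inactive.

    This is the reduced-space analogue of a frozen-core treatment: the
    frozen occupieds enter only through the Fock matrix.
    """
    n_ao = C.shape[0]
    occ_idx = [i for i in range(n_occ) if i not in frozen_occ]
    return OrbitalSpace(
        C_occ_act=C[:, occ_idx],
        C_occ_inact=C[:, sorted(frozen_occ)],
        C_virt_act=C[:, n_occ:],
        C_virt_inact=np.zeros((n_ao, 0)),
    )
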