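"""EOM oscillator strengths and broadened absorption spectra.

The transition strength between the CC ground state and excited state k is

    f_k = (2/3) * omega_k * sum_alpha <L0|mubar^alpha|R^k> <L^k|mubar^alpha|R0>

with mubar = exp(-T) mu exp(T). Matrix elements of the similarity-
transformed one-body operator are generated by running the ground-state
residual and Jacobian machinery with the dipole matrix in place of the Fock
matrix and zero two-electron integrals: <mu|mubar|HF> is then exactly the
"residual" of mubar, and the amplitude-block action follows from the
Jacobian linearization plus the disconnected reference and singles-product
terms. Both left and right moments are reported; their product may in rare
cases be slightly negative for truncated CC, in which case f is reported
as-is with a warning rather than clipped.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ccsd import ccsd_residual
from .constants import HARTREE_TO_EV
from .eom import EOMState, GroundStateLambda, JacobianOperator, cc_dot
from .moints import SpinOrbitalHamiltonian


@dataclass
class TransitionRecord:
    """Energies, left/right transition moments and oscillator strength."""

    index: int
    omega_ev: float
    moments_right: np.ndarray  # <L0|mubar^a|Rk>, a = x,y,z
    moments_left: np.ndarray   # <Lk|mubar^a|R0>
    f: float


class _OneBodyBar:
    """Similarity-transformed one-body operator over fixed amplitudes."""

    def __init__(self, H: SpinOrbitalHamiltonian, m_blocks, t1, t2, t2_mask=None):
        z2 = np.zeros_like(H.ooov)
        Hm = SpinOrbitalHamiltonian(
            nocc=H.nocc, nvirt=H.nvirt,
            f_oo=m_blocks["oo"], f_ov=m_blocks["ov"], f_vv=m_blocks["vv"],
            oooo=np.zeros_like(H.oooo), ooov=z2,
            oovv=np.zeros_like(H.oovv), ovov=np.zeros_like(H.ovov),
            ovvv=np.zeros_like(H.ovvv), vvvv=np.zeros_like(H.vvvv),
        )
        self.t1, self.t2 = t1, t2
        self.m_ov = m_blocks["ov"]
        self.ref_value = float(np.trace(m_blocks["oo"]) + np.sum(m_blocks["ov"] * t1))
        xi1, xi2 = ccsd_residual(Hm, t1, t2, t2_mask)
        self.xi = (xi1, xi2)
        self.op = JacobianOperator(Hm, t1, t2, t2_mask=t2_mask)

    def block_apply(self, x):
        """<mu|mubar tau_nu|HF> contracted with x."""
        s1, s2 = self.op.apply(x)
        s1 = s1 + self.ref_value * x[0]
        s2 = s2 + self.ref_value * x[1]
        # tau_nu tau_sigma |HF> disconnected singles-product contribution
        X = np.einsum("ia,jb->ijab", x[0], self.xi[0])
        s2 = s2 + (
            X - X.transpose(0, 1, 3, 2) - X.transpose(1, 0, 2, 3)
            + X.transpose(1, 0, 3, 2)
        )
        return (s1, s2)

    def eta_dot(self, x) -> float:
        """<HF|[mubar, tau_nu]|HF> . x (only singles survive)."""
        return float(np.sum(self.m_ov * x[0]))

    def ground_expectation(self, lam: GroundStateLambda) -> float:
        """<L0|mubar|R0> = M00 + l0 . xi."""
        return self.ref_value + cc_dot((lam.l1, lam.l2), self.xi)


def transition_strength(
    state: EOMState,
    lam: GroundStateLambda,
    H: SpinOrbitalHamiltonian,
    t1: np.ndarray,
    t2: np.ndarray,
    index: int = 0,
    t2_mask: np.ndarray | None = None,
    bars: list[_OneBodyBar] | None = None,
) -> TransitionRecord:
    """Oscillator strength for one biorthonormalized EOM state."""
    if state.l1 is None or not state.biorthonormalized:
        raise ValueError("state must carry a biorthonormalized left vector")
    if not H.dip_blocks and bars is None:
        raise ValueError("Hamiltonian carries no dipole integrals")
    if bars is None:
        bars = [_OneBodyBar(H, mb, t1, t2, t2_mask) for mb in H.dip_blocks]
    r = (state.r1, state.r2)
    l = (state.l1, state.l2)
    l0 = (lam.l1, lam.l2)
    tr = np.empty(3)
    tl = np.empty(3)
    for a, bar in enumerate(bars):
        Mr = bar.block_apply(r)
        tr[a] = (
            state.r0 * bar.ref_value
            + bar.eta_dot(r)
            + state.r0 * cc_dot(l0, bar.xi)
            + cc_dot(l0, Mr)
        )
        tl[a] = cc_dot(l, bar.xi)
    f = 2.0 / 3.0 * state.omega * float(tr @ tl)
    if f < -1e-12:
        warnings.warn(
            f"negative oscillator strength {f:.3e} for state {index} "
            "(non-Hermitian left/right product); reported unclipped",
            stacklevel=2,
        )
    return TransitionRecord(
        index=index,
        omega_ev=state.omega * HARTREE_TO_EV,
        moments_right=tr,
        moments_left=tl,
        f=f,
    )


def transition_strengths(
    states: list[EOMState],
    lam: GroundStateLambda,
    H: SpinOrbitalHamiltonian,
    t1: np.ndarray,
    t2: np.ndarray,
    t2_mask: np.ndarray | None = None,
) -> list[TransitionRecord]:
    bars = [_OneBodyBar(H, mb, t1, t2, t2_mask) for mb in H.dip_blocks]
    return [
        transition_strength(s, lam, H, t1, t2, index=k, t2_mask=t2_mask, bars=bars)
        for k, s in enumerate(states)
    ]


# ---------------------------------------------------------------------------
# broadening and I/O
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """Stick spectrum plus Lorentzian-broadened curve on an eV grid."""

    sticks: np.ndarray      # (n, 2): energy_eV, oscillator strength
    grid: np.ndarray        # strictly increasing energies (eV)
    intensity: np.ndarray   # broadened curve
    fwhm: float             # eV


def broaden(
    sticks,
    fwhm_ev: float = 0.3,
    grid: np.ndarray | None = None,
    margin: float = 5.0,
    n_points: int = 2000,
) -> Spectrum:
    """Sum of area-normalized Lorentzians, gamma = FWHM/2, one per stick."""
    if fwhm_ev <= 0:
        raise ValueError("FWHM must be positive")
    sticks = np.atleast_2d(np.asarray(sticks, float))
    if sticks.size == 0:
        sticks = np.zeros((0, 2))
    if grid is None:
        if len(sticks):
            lo = sticks[:, 0].min() - margin
            hi = sticks[:, 0].max() + margin
        else:
            lo, hi = 0.0, 1.0
        grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("energy grid must be strictly increasing")
    gamma = fwhm_ev / 2.0
    curve = np.zeros_like(grid)
    for e0, f in sticks:
        curve += f * (gamma / np.pi) / ((grid - e0) ** 2 + gamma**2)
    return Spectrum(sticks=sticks, grid=grid, intensity=curve, fwhm=fwhm_ev)


def spectrum_from_records(
    records: list[TransitionRecord], fwhm_ev: float = 0.3, **kw
) -> Spectrum:
    sticks = np.array([[r.omega_ev, r.f] for r in records]).reshape(-1, 2)
    return broaden(sticks, fwhm_ev, **kw)


def write_spectrum(spec: Spectrum, path, shift_ev: float | None = None) -> None:
    """CSV output: a stick table then the broadened curve.

    ``shift_ev`` adds an optional uniform-shift column for comparison with
    experiment; it is presentation only and off by default.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["energy_eV", "oscillator_strength"]
        if shift_ev is not None:
            header.append("energy_shifted_eV")
        w.writerow(["# sticks"])
        w.writerow(header)
        for e, f in spec.sticks:
            row = [repr(float(e)), repr(float(f))]
            if shift_ev is not None:
                row.append(repr(float(e + shift_ev)))
            w.writerow(row)
        w.writerow(["# curve", f"fwhm_eV={spec.fwhm}"])
        w.writerow(["energy_eV", "intensity"])
        for e, y in zip(spec.grid, spec.intensity):
            w.writerow([repr(float(e)), repr(float(y))])


def read_spectrum(path) -> Spectrum:
    """Re-read a spectrum written by :func:`write_spectrum` (lossless)."""
    sticks, curve = [], []
    section = None
    fwhm = 0.3
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            if row[0] == "# sticks":
                section = "sticks"
                continue
            if row[0] == "# curve":
                section = "curve"
                if len(row) > 1 and row[1].startswith("fwhm_eV="):
                    fwhm = float(row[1].split("=", 1)[1])
                continue
            if row[0].startswith("energy"):
                continue
            if section == "sticks":
                sticks.append([float(row[0]), float(row[1])])
            elif section == "curve":
                curve.append([float(row[0]), float(row[1])])
    curve = np.asarray(curve)
    return Spectrum(
        sticks=np.asarray(sticks).reshape(-1, 2),
        grid=curve[:, 0] if len(curve) else np.array([]),
        intensity=curve[:, 1] if len(curve) else np.array([]),
        fwhm=fwhm,
    )
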