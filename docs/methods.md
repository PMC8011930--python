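# Methods

This note describes the models implemented in `ccxas`, the numerical
choices behind them, and what the built-in test systems do and do not
demonstrate.

## Models

**Ground state.** The coupled-cluster wave function is
`|CC> = exp(X)|HF>` over a closed-shell RHF determinant; the amplitudes
solve the projected equations `Omega_mu = <mu| e^{-X} H e^{X} |HF> = 0` and
the energy is `<HF| e^{-X} H e^{X} |HF>`. Three truncations are provided:

* **CCSD** — X = T1 + T2 over all orbitals.
* **MLCCSD (CCS/CCSD)** — T1 spans all orbitals; T2 *and the doubles
  projection space* are restricted to an active orbital set. This is
  realized by masking: the doubles amplitudes and doubles residual are
  zeroed outside the active index pattern every iteration. The solutions
  are identical to those of a dedicated restricted solver; only the cost
  profile differs, which is out of scope here.
* **CCSD-in-HF** — both T1 and T2 restricted to the active set, which is
  equivalent to ordinary CCSD in a truncated MO basis. The inactive
  occupied orbitals enter through the effective Fock matrix: because the
  AO Fock operator is built from the full occupied density, its
  active-block MO representation already carries the inactive-occupied
  Coulomb/exchange field. Total energies are reported as
  `E_HF(full) + E_corr(active)`, which makes the full-active limit agree
  with CCSD to machine precision. No correlation correction for the
  inactive space is added.

The working equations are spin-orbital singles/doubles equations with the
standard one- and two-body intermediates, written with the *full*
(non-diagonal) Fock matrix so that semicanonical and reduced-space
references need no special casing. The amplitude update is quasi-Newton
with semicanonical orbital-energy denominators and DIIS (depth 8) over the
concatenated amplitude vector; the initial guess is MP2 within the allowed
space. Convergence defaults: 1e-6 on the residual norm plus 1e-8 on the
energy change.

**Excited states.** EOM states are eigenpairs of the Jacobian
`A_{mu,nu} = <mu|[Hbar, tau_nu]|HF>`. The implementation applies A
matrix-free as the exact analytic directional derivative of the residual
code (`A r = d/ds Omega(t + s r)`), and `A^T` as the corresponding
reverse-mode adjoint; both are verified in the tests against a
polynomial-exact finite-difference rule, an adjoint identity, and an
explicit determinant-space similarity transform. Left and right
eigenvectors are biorthonormalized blockwise (`L^k . R^l = delta_kl`,
degenerate blocks paired by inverting the small overlap matrix), and the
scalar part of the right vector is `r0 = -l0 . r_k`, with the ground-state
multipliers `l0` solving `A^T l0 = -eta` by preconditioned iteration with
DIIS.

**Core-valence separation.** Core-excited states are isolated by
projection: every singles element whose occupied index is not a core
orbital, and every doubles element with no core occupied index, is zeroed
in the trial vectors, residuals and preconditioned corrections. The
multiplier equations are solved *without* CVS (the ground state is a
valence object); the left core-excited states carry the CVS projection,
following common practice in the CVS literature. The target core orbital
is identified by its Mulliken population on the atom's core s-type AO
(tie tolerance 0.05, ambiguity is an error), which is well defined in the
semicanonical basis because 1s orbitals barely mix.

**Oscillator strengths.** Length gauge,

    f_k = (2/3) omega_k sum_alpha <L0|mubar^a|R^k> <L^k|mubar^a|R0>,

with `mubar = e^{-T} mu e^{T}`. Matrix elements of the similarity-
transformed dipole are generated by running the residual and Jacobian
machinery with the dipole matrix in place of the Fock matrix and zero
two-electron integrals, plus the disconnected reference and
singles-product terms; this is algebraically identical to the usual
one-particle transition-density route and is validated against FCI on
two-electron systems (where EOM-CCSD is exact). The dipole origin is the
center of nuclear charge; for transitions between biorthonormal states any
constant (nuclear) term drops exactly, and origin dependence of truncated
CC strengths is therefore pinned to this convention. The left/right
moment product can in principle be slightly negative for truncated CC;
negative f is reported as-is with a warning.

## Orbital partitioning

* **Occupied:** pivoted Cholesky decomposition of the idempotent HF
  density with pivots restricted to AOs on the active atoms (largest
  diagonal first, ties to the lowest AO index), terminated when all
  active diagonals fall below the threshold (default 1e-2; because the
  rank of the idempotent density is integer-valued the split is robust
  over a wide threshold range, and the largest neglected diagonal is
  reported). The residual inactive density is then fully decomposed
  (internal rank tolerance 1e-8). Idempotency makes the factors
  S-orthonormal; each block is canonically re-orthonormalized for
  numerical hygiene.
* **Active virtuals:** projected atomic orbitals, `(1 - D S)` applied to
  the active-atom AO columns, followed by Lowdin canonical
  orthonormalization with metric-eigenvalue cutoff 1e-6 (reported as the
  PAO rank deficit).
* **Inactive virtuals:** the orthonormalized complement of
  occupied + active-virtual within the MO span; a rank mismatch raises a
  partition-inconsistency error.
* **Semicanonicalization:** the occupied-occupied and virtual-virtual
  Fock blocks are diagonalized by rotations within each of the four
  blocks separately (never mixing active with inactive or occupied with
  virtual); degenerate eigenvalues are ordered by (energy, original
  index) so results are reproducible. AO linear dependence is removed by
  canonical orthonormalization of the overlap (cutoff 1e-8) before any of
  this.

## Eigensolver for the CVS window

The CVS-projected Jacobian is strongly non-normal: its field of values
extends far below its spectrum, so a naive "take the lowest Ritz value"
Davidson locks onto spurious oblique-projection values that drift through
and below the physical window. Three safeguards are used, all exercised by
the tests:

1. start vectors are the exact eigenvectors of the singles-singles block
   restricted to the allowed window (a CIS-like problem solved densely);
2. roots are followed across iterations by projection onto the span of the
   previous Ritz vectors, with a two-root buffer so degenerate shells at
   the requested cutoff cannot shed members;
3. (near-)degenerate clusters are treated blockwise — an orthonormal
   cluster basis X with block matrix `B = X^T A X` and block residual
   `A X - X B` — making convergence invariant to the arbitrary mixing of
   eigenvectors inside a cluster.

Under CVS the vectors are stored compressed on the core occupied rows
(the rest is fixed by antisymmetry), which shrinks the subspace algebra by
roughly `(n_occ/n_core)^1`. Corrections are preconditioned with
orbital-energy-difference denominators level-shifted away from zero by
0.01 Hartree, and the Gram-Schmidt steps run two passes (a single pass
loses orthogonality on nearly dependent corrections). Default thresholds
follow standard practice for this class of calculation: 1e-4 on the
residual and 1e-6 on the energy change.

Spin is handled by sector projection rather than spin-adapted equations:
the Jacobian over a closed-shell reference commutes with total spin, so
restricting guesses and corrections to the Sz = 0, spin-flip-even sector
(`spin="singlet"`, the default of the high-level driver) converges singlet
roots only — these are what "n roots per atom" counts in K-edge work,
since triplets are dark. `spin="both"` recovers the full spectrum and is
what the FCI-comparison tests use.

## Integrals and reference

A built-in McMurchie–Davidson engine (numba-compiled kernels; Boys
function by series/downward recursion below x = 35 and asymptotic/upward
recursion above) supplies overlap, kinetic, nuclear-attraction, dipole and
two-electron integrals over contracted cartesian Gaussians, plus RHF with
DIIS. The shipped basis tables are the published STO-3G (H, He, C, N, O)
and 6-31G (H, C, N, O) parameter sets — adequate for the desk-scale
systems this package targets, with mixed per-atom assignments
(bigger basis on the chromophore) as a first-class feature. The ERI
Cholesky decomposition (default threshold 1e-6, 1e-8 available) is
provided for the interchange pathway; the correlation modules consume the
full MO integral blocks directly at these system sizes.

Units: Hartree and Bohr internally, Angstrom in XYZ I/O, eV only at the
reporting layer (1 Hartree = 27.211386245988 eV).

## Synthetic test systems

The fixture roster (`h2`, `he`, `h2o`, `methylamine`, `methylamine_w2`,
`methylamine_w8`, `dimer_separated`) is generated from standard bond
parameters and hand-placed hydrogen-bonded water shells. The solvated
methylamine systems emulate the situation core-excitation studies care
about — a nitrogen chromophore perturbed by explicit solvent, treated at a
mixed basis (split-valence 6-31G on the chromophore heavy atoms, minimal
elsewhere) — at a scale where full CCSD is still cheap enough to serve as
the in-house reference. What they do not emulate: diffuse (Rydberg)
character of higher core-excited states (no augmented functions),
geometry/ensemble sampling of a real solvent, relativistic corrections to
absolute edge positions, or the basis-set maturity of production studies;
conclusions about *relative* accuracy (multilevel vs full CCSD on the same
Hamiltonian) transfer, absolute edge energies do not.

## Problem sizes and verification

The headline check runs methylamine + 2 waters (37 AOs, 19 occupied
orbitals), partitions with the methylamine atoms active (9 active + 10
inactive occupied; the PAOs span the whole 18-orbital virtual space at
this basis), and compares the six lowest singlet CVS nitrogen-1s
excitation energies of MLCCSD and CCSD-in-HF against full CCSD; both stay
within a few hundredths of an eV. Independent verification is layered:
brute-force FCI (Slater–Condon, dense diagonalization) pins two-electron
energies and oscillator strengths; a determinant-space similarity
transform — building `e^{-T} H e^{T}` as explicit matrices via fermionic
operator algebra — pins the residual, Jacobian, eta vector and multipliers
at four-electron scale to machine precision; limit equivalences
(full-active multilevel = CCSD, frozen-1s CCSD-in-HF = frozen-core CCSD
built independently from the bare one-electron integrals) pin the
reduced-space bookkeeping.

## Known limitations

* No triples (CC2/CC3), no response-theory (vs EOM) strengths, no triplet
  spectra through the high-level driver, no open-shell references.
* The restriction-by-masking MLCCSD implementation reproduces the model's
  *solutions*, not its computational scaling; wall-time claims of
  multilevel methods are outside scope.
* Cartesian d or higher shells are supported by the integral kernels but
  no shipped basis set uses them; correlation-consistent sets are not
  bundled.
* The Cholesky ERI factors are not yet consumed by the correlation
  modules (full MO blocks are used); at the target system sizes this is
  immaterial.
* One CVS window (one core-excited atom) per run; multi-atom edges are
  produced by looping runs, mirroring how per-atom K-edge calculations
  are organized in practice.
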