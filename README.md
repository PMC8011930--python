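# ccxas

Coupled-cluster core-excitation (NEXAFS-style K-edge) spectra at desk
scale, for method developers and students who want a fully transparent,
fully tested reference implementation of multilevel coupled-cluster
excited-state theory:

* **CCSD** ground and EOM excited states over a closed-shell RHF reference;
* **MLCCSD (CCS/CCSD)** — single excitations everywhere, double
  excitations (and the doubles projection space) restricted to an active
  orbital set;
* **CCSD-in-HF** — CCSD in a truncated active MO basis, the inactive
  occupied orbitals entering only through the effective Fock matrix;
* **Cholesky/PAO partitioning** — active occupied orbitals from a
  restricted-pivot Cholesky decomposition of the idempotent HF density,
  active virtuals from projected atomic orbitals on the active atoms,
  followed by block semicanonicalization;
* **CVS** (core-valence separation) to isolate core-excited roots, EOM
  oscillator strengths from biorthonormal left/right states, and
  Lorentzian-broadened spectra (0.3 eV FWHM default).

Everything runs on a laptop: a built-in McMurchie–Davidson integral engine
(numba kernels) and RHF reference feed the correlation modules, so there is
no external quantum-chemistry dependency. An HDF5 interchange format and an
FCIDUMP writer keep the package engine-independent.

## The model in brief

With `|CC> = e^X |HF>` and `Hbar = e^{-X} H e^X`, the amplitudes solve
`<mu|Hbar|HF> = 0` and excited states are eigenpairs of the Jacobian
`A_{mu,nu} = <mu|[Hbar, tau_nu]|HF>`, with distinct left (`L^k`) and right
(`R^k`) eigenvectors normalized to `L^k . R^l = delta_kl`. MLCCSD restricts
the T2 block of X (and the doubles rows of A) to active orbitals; CCSD-in-HF
restricts everything. Core-excited states are obtained by projecting the
eigenproblem onto vectors with at least one core occupied index (CVS), and
intensities follow the EOM expression

    f_k = (2/3) omega_k sum_a <L0|mubar^a|R^k><L^k|mubar^a|R0>.

See `docs/methods.md` for the complete account, including the
non-normality safeguards in the CVS eigensolver.

## Worked example

`examples/01_water_valence_states.py` (seconds):

```
RHF energy        -75.98397447 Ha
CCSD energy       -76.11935396 Ha (correlation -0.13537950)

singlet valence states (energy in eV, oscillator strength):
  S1:   8.3882 eV   f = 0.013578
  S2:  10.6673 eV   f = -0.000000
  S3:  10.9272 eV   f = 0.115177
  S4:  13.3732 eV   f = 0.113896
```

The first band is the weak n->3s-like transition of water; f ~ 0 marks a
symmetry-forbidden state. `examples/03_nitrogen_kedge_multilevel.py`
(a few minutes) runs the headline workflow — methylamine + two waters,
methylamine active — and prints the six lowest CVS nitrogen-1s roots for
all three methods; the multilevel energies track full CCSD to a few
hundredths of an eV:

```
ccsd: E_total = -245.359233 Ha
  root 0:  408.7712 eV  f = 0.02246
  root 1:  412.3157 eV  f = 0.07723
  ...
max |mlccsd - ccsd| = 0.0660 eV
max |ccsd-in-hf - ccsd| = 0.0648 eV
```

There is also a thin CLI for configuration-driven runs:

```bash
ccxas fixtures                       # list built-in geometries
ccxas run config.yaml                # geometry -> partition -> CCSD -> CVS -> spectrum
ccxas partition-report config.yaml   # active/inactive orbital counts
ccxas spectrum run/states.tsv --fwhm 0.3
```

## Layout

```
src/ccxas/      integrals, scf, partition, ccsd, eom, spectra, fci (oracles),
                methods (drivers), workflow, cli, fixtures, interchange
examples/       four narrative scripts, one per capability
tests/          pytest suite; test_acceptance.py holds the headline checks
docs/methods.md the models, numerics and limitations in full
```
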