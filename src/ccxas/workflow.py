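"""Configuration-driven end-to-end runs: geometry -> partition -> ground
state -> CVS EOM -> broadened spectrum.

One run handles one CVS window (one core-excited atom); production studies
loop over the edge atoms with one calculation each, writing a manifest, a
state table and spectrum files into the output directory.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .basis import BasisAssignment, aos_on_atoms, build_shells
from .ccsd import METHODS
from .constants import HARTREE_TO_EV
from .fixtures import make_fixture
from .methods import (GroundStateResult, make_cvs_spec, solve_excited_states,
                      solve_ground_state)
from .molecule import Molecule, load_geometry
from .partition import (ActiveAtomSelection, full_active_space,
                        partition_orbital_space)
from .scf import compute_reference
from .spectra import spectrum_from_records, write_spectrum


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """One end-to-end calculation. Thresholds default to the standard values
    used throughout this package: 1e-6 on the ground-state residual, 1e-4 /
    1e-6 on the excited-state residual / energy change, 0.3 eV FWHM."""

    geometry: str = ""                 # path to an XYZ file, or fixture:<name>
    method: str = "ccsd"
    basis: dict = field(default_factory=lambda: {"default": "sto-3g"})
    active_atoms: list = field(default_factory=list)
    core_atoms: list = field(default_factory=list)  # atom indices (K edges)
    n_roots_per_atom: int = 6
    ground_tol: float = 1e-6
    excited_res_tol: float = 1e-4
    excited_e_tol: float = 1e-6
    occ_cholesky_threshold: float = 1e-2
    pao_lindep_tol: float = 1e-6
    eri_cholesky_threshold: float = 1e-6
    fwhm_ev: float = 0.3
    oscillator_strengths: bool = True
    write_interchange: bool = False
    output_dir: str = "ccxas_run"

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method != "ccsd" and not self.active_atoms:
            raise ConfigError(f"{self.method} requires an active_atoms list")
        if not self.geometry:
            raise ConfigError("geometry is required")
        for name, v in (
            ("ground_tol", self.ground_tol),
            ("excited_res_tol", self.excited_res_tol),
            ("excited_e_tol", self.excited_e_tol),
            ("occ_cholesky_threshold", self.occ_cholesky_threshold),
            ("pao_lindep_tol", self.pao_lindep_tol),
            ("eri_cholesky_threshold", self.eri_cholesky_threshold),
            ("fwhm_ev", self.fwhm_ev),
        ):
            if v <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True,
        )


def _load_molecule(geometry: str) -> Molecule:
    if geometry.startswith("fixture:"):
        return make_fixture(geometry.split(":", 1)[1]).molecule
    return load_geometry(Path(geometry).read_text())


def core_orbital_resolve(
    C_occ: np.ndarray,
    S: np.ndarray,
    shells,
    atom_index: int,
    tie_tol: float = 0.05,
) -> int:
    """Occupied orbital with the largest Mulliken population on the atom's
    core (first s-type) AO; ambiguity within ``tie_tol`` is an error."""
    atom_shells = [sh for sh in shells if sh.atom_index == atom_index]
    if not atom_shells:
        raise ValueError(f"atom {atom_index} carries no basis functions")
    heavy = [sh for sh in atom_shells if sh.l == 0]
    # hydrogen/helium have no distinct core shell below the valence space
    ao_off = 0
    core_ao = None
    for sh in shells:
        if sh.atom_index == atom_index and sh.l == 0:
            core_ao = ao_off
            break
        ao_off += sh.n_functions
    if core_ao is None or len(heavy) < 2:
        raise ValueError(
            f"atom {atom_index} has no resolvable 1s core orbital"
        )
    SC = S @ C_occ
    pops = np.abs(SC[core_ao] * C_occ[core_ao])
    order = np.argsort(pops)[::-1]
    if len(order) > 1 and pops[order[0]] - pops[order[1]] < tie_tol:
        raise ValueError(
            f"ambiguous core-orbital resolution for atom {atom_index}: "
            f"populations {pops[order[0]]:.3f} vs {pops[order[1]]:.3f}; "
            "specify the orbital index explicitly"
        )
    return int(order[0])


def partition_report(config: RunConfig) -> dict:
    """Counts and diagnostics of the Cholesky/PAO partition for a config."""
    config.validate()
    if not config.active_atoms:
        raise ConfigError("partition report requires active_atoms")
    mol = _load_molecule(config.geometry)
    basis = BasisAssignment(**config.basis)
    ints, scf = compute_reference(mol, basis)
    shells = build_shells(mol, basis)
    sel = ActiveAtomSelection.from_atoms(shells, config.active_atoms)
    space, rep = partition_orbital_space(
        scf.density(), ints.S, scf.fock_ao(ints), scf.n_mo, sel,
        occ_threshold=config.occ_cholesky_threshold,
        pao_lindep_tol=config.pao_lindep_tol,
    )
    return rep.as_dict()


def run(config: RunConfig) -> dict:
    """Execute a config; returns the manifest (also written to disk)."""
    config.validate()
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name):
        stages.append({"stage": name, "t": round(time.time() - t_start, 2)})

    mol = _load_molecule(config.geometry)
    basis = BasisAssignment(**config.basis)
    ints, scf = compute_reference(mol, basis)
    shells = build_shells(mol, basis)
    if config.write_interchange:
        from .integrals import cholesky_decompose_eri
        from .interchange import dump_interchange

        ints.cholesky = cholesky_decompose_eri(
            ints.g, config.eri_cholesky_threshold
        )
        dump_interchange(ints, scf, outdir / "reference.h5")
    stage("reference")

    if config.active_atoms:
        sel = ActiveAtomSelection.from_atoms(shells, config.active_atoms)
        space, rep = partition_orbital_space(
            scf.density(), ints.S, scf.fock_ao(ints), scf.n_mo, sel,
            occ_threshold=config.occ_cholesky_threshold,
            pao_lindep_tol=config.pao_lindep_tol,
        )
        partition = rep.as_dict()
        limit_equivalent = (
            space.n_occ_inact == 0 and space.n_virt_inact == 0
        )
    else:
        space = full_active_space(scf.C, scf.n_occ, scf.eps)
        partition = None
        limit_equivalent = True
    stage("partition")

    res = solve_ground_state(
        ints, scf, config.method, space, conv_tol=config.ground_tol
    )
    stage("ground_state")

    roots = []
    spectrum_rows = []
    n_occ_calc = res.H.nocc // 2
    C_occ_calc = (
        np.hstack([space.C_occ_act, space.C_virt_act])[:, : space.n_occ_act]
        if config.method == "ccsd-in-hf"
        else res.space.C_full[:, : n_occ_calc]
    )
    for atom in config.core_atoms:
        core_idx = core_orbital_resolve(C_occ_calc, ints.S, shells, atom)
        cvs = make_cvs_spec(res, [core_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ex = solve_excited_states(
                res, config.n_roots_per_atom, cvs=cvs,
                res_tol=config.excited_res_tol, e_tol=config.excited_e_tol,
                with_oscillator_strengths=config.oscillator_strengths,
            )
        for k, st in enumerate(ex.states):
            row = {
                "atom": atom,
                "core_orbital": core_idx,
                "root": k,
                "omega_hartree": st.omega,
                "omega_ev": st.omega * HARTREE_TO_EV,
                "residual": st.residual,
            }
            if config.oscillator_strengths:
                row["f"] = ex.records[k].f
                spectrum_rows.append((row["omega_ev"], row["f"]))
            roots.append(row)
        stage(f"cvs_atom_{atom}")

    if spectrum_rows:
        spec = spectrum_from_records(
            [type("R", (), {"omega_ev": e, "f": f})() for e, f in spectrum_rows],
            fwhm_ev=config.fwhm_ev,
        )
        write_spectrum(spec, outdir / "spectrum.csv")

    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "n_ao": ints.n_ao,
        "n_mo": scf.n_mo,
        "e_hf": scf.e_hf,
        "method": config.method,
        "partition": partition,
        "limit_equivalent_to_ccsd": limit_equivalent,
        "e_corr": res.state.e_corr,
        "e_total": res.state.e_total,
        "ground_iterations": res.state.n_iter,
        "ground_residual": res.state.residual_norm,
        "roots": roots,
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    with open(outdir / "states.tsv", "w") as f:
        cols = ["atom", "core_orbital", "root", "omega_hartree", "omega_ev",
                "residual"] + (["f"] if config.oscillator_strengths else [])
        f.write("\t".join(cols) + "\n")
        for row in roots:
            f.write("\t".join(repr(row[c]) for c in cols) + "\n")
    return manifest
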