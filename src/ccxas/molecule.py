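"""Molecular geometry container and XYZ parsing (Angstrom in, Bohr inside)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, ATOMIC_NUMBERS


class GeometryParseError(ValueError):
    """Raised for malformed XYZ input, naming the offending line."""


@dataclass
class Molecule:
    """A molecule: element symbols, coordinates (Angstrom), charge, multiplicity.

    Only closed-shell (multiplicity 1) references are supported downstream.
    """

    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    charge: int = 0
    multiplicity: int = 1
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) == 0:
            raise ValueError("molecule must contain at least one atom")
        if len(self.symbols) != self.coords.shape[0]:
            raise ValueError("symbol/coordinate count mismatch")
        for s in self.symbols:
            if s not in ATOMIC_NUMBERS:
                raise ValueError(f"unknown element symbol {s!r}")
        if self.multiplicity != 1:
            raise ValueError("only closed-shell (multiplicity 1) molecules are supported")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.symbols], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANGSTROM_TO_BOHR

    def nuclear_repulsion(self) -> float:
        """Nuclear repulsion energy in Hartree."""
        z = self.atomic_numbers.astype(float)
        r = self.coords_bohr
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def center_of_nuclear_charge(self) -> np.ndarray:
        """Center of nuclear charge in Bohr (the dipole-operator origin)."""
        z = self.atomic_numbers.astype(float)
        return (z[:, None] * self.coords_bohr).sum(axis=0) / z.sum()

    def to_xyz(self) -> str:
        lines = [str(self.n_atoms), self.comment]
        for s, xyz in zip(self.symbols, self.coords):
            lines.append(f"{s:<3s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}")
        return "\n".join(lines) + "\n"


def load_geometry(xyz_text: str, charge: int = 0, multiplicity: int = 1) -> Molecule:
    """Parse a standard XYZ block (count line, comment line, atom lines).

    Coordinates are taken in Angstrom. Raises :class:`GeometryParseError`
    naming the line on malformed input or unknown elements.
    """
    lines = xyz_text.splitlines()
    if not lines:
        raise GeometryParseError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryParseError(f"line 1: expected atom count, got {lines[0]!r}") from exc
    if len(lines) < n + 2:
        raise GeometryParseError(f"expected {n} atom lines, found {max(len(lines) - 2, 0)}")
    comment = lines[1] if len(lines) > 1 else ""
    symbols: list[str] = []
    coords = np.zeros((n, 3))
    for k in range(n):
        ln = lines[2 + k]
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryParseError(f"line {3 + k}: malformed atom line {ln!r}")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise GeometryParseError(f"line {3 + k}: unknown element {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise GeometryParseError(f"line {3 + k}: bad coordinates in {ln!r}") from exc
        symbols.append(sym)
        coords[k] = xyz
    return Molecule(symbols, coords, charge=charge, multiplicity=multiplicity, comment=comment)
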