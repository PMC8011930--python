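"""Gaussian basis sets and per-atom basis assignment.

The shipped tables are the published Pople basis sets (STO-3G, 6-31G) for the
elements the desk-scale fixtures need. Exponents are in inverse square Bohr;
contraction coefficients refer to normalized primitives, and each contracted
function is renormalized numerically.

Cartesian angular ordering follows the common (x, y, z) convention for p
shells; only s and p shells appear in the shipped sets, although the integral
kernels are general.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule import Molecule

# name -> element -> list of (l, [exponents], [coefficients])
BASIS_LIBRARY: dict[str, dict[str, list[tuple[int, list[float], list[float]]]]] = {
    "sto-3g": {
        "H": [
            (0, [3.42525091, 0.62391373, 0.16885540],
                [0.15432897, 0.53532814, 0.44463454]),
        ],
        "He": [
            (0, [6.36242139, 1.15892300, 0.31364979],
                [0.15432897, 0.53532814, 0.44463454]),
        ],
        "C": [
            (0, [71.61683735, 13.04509632, 3.53051216],
                [0.15432897, 0.53532814, 0.44463454]),
            (0, [2.94124940, 0.68348310, 0.22228990],
                [-0.09996723, 0.39951283, 0.70011547]),
            (1, [2.94124940, 0.68348310, 0.22228990],
                [0.15591627, 0.60768372, 0.39195739]),
        ],
        "N": [
            (0, [99.10616896, 18.05231239, 4.88566024],
                [0.15432897, 0.53532814, 0.44463454]),
            (0, [3.78045590, 0.87849664, 0.28571434],
                [-0.09996723, 0.39951283, 0.70011547]),
            (1, [3.78045590, 0.87849664, 0.28571434],
                [0.15591627, 0.60768372, 0.39195739]),
        ],
        "O": [
            (0, [130.70932140, 23.80886605, 6.44360831],
                [0.15432897, 0.53532814, 0.44463454]),
            (0, [5.03315132, 1.16959612, 0.38038896],
                [-0.09996723, 0.39951283, 0.70011547]),
            (1, [5.03315132, 1.16959612, 0.38038896],
                [0.15591627, 0.60768372, 0.39195739]),
        ],
    },
    "6-31g": {
        "H": [
            (0, [18.73113696, 2.82539437, 0.64012169],
                [0.03349460, 0.23472695, 0.81375733]),
            (0, [0.16127776], [1.0]),
        ],
        "C": [
            (0, [3047.52488, 457.36951800, 103.94868500, 29.21015530,
                 9.28666296, 3.16392696],
                [0.00183474, 0.01403732, 0.06884262, 0.23218444,
                 0.46794135, 0.36231199]),
            (0, [7.86827235, 1.88128854, 0.54424926],
                [-0.11933242, -0.16085415, 1.14345644]),
            (1, [7.86827235, 1.88128854, 0.54424926],
                [0.06899907, 0.31642396, 0.74430829]),
            (0, [0.16871448], [1.0]),
            (1, [0.16871448], [1.0]),
        ],
        "N": [
            (0, [4173.51146, 627.45791100, 142.90209300, 40.23432930,
                 13.12984540, 4.25033763],
                [0.00183477, 0.01399463, 0.06858655, 0.23224087,
                 0.46906995, 0.36045520]),
            (0, [11.74876876, 2.67598812, 0.69809920],
                [-0.11496118, -0.16911748, 1.14585195]),
            (1, [11.74876876, 2.67598812, 0.69809920],
                [0.06757974, 0.32390730, 0.74089514]),
            (0, [0.21203150], [1.0]),
            (1, [0.21203150], [1.0]),
        ],
        "O": [
            (0, [5484.67166, 825.23494600, 188.04695800, 52.96450000,
                 16.89757040, 5.79963534],
                [0.00183107, 0.01395017, 0.06844508, 0.23271434,
                 0.47019290, 0.35852085]),
            (0, [15.53961625, 3.59993359, 1.01376175],
                [-0.11077755, -0.14802626, 1.13076702]),
            (1, [15.53961625, 3.59993359, 1.01376175],
                [0.07087427, 0.33975284, 0.72715858]),
            (0, [0.27000582], [1.0]),
            (1, [0.27000582], [1.0]),
        ],
    },
}


@dataclass
class BasisAssignment:
    """Basis set per atom: explicit per-atom or per-element names over a default.

    ``per_atom`` maps atom index to basis name; ``per_element`` maps element
    symbols. Lookup order: per_atom, per_element, default.
    """

    default: str = "sto-3g"
    per_element: dict[str, str] | None = None
    per_atom: dict[int, str] | None = None

    def resolve(self, atom_index: int, symbol: str) -> str:
        if self.per_atom and atom_index in self.per_atom:
            return self.per_atom[atom_index]
        if self.per_element:
            for key in (symbol, symbol.capitalize()):
                if key in self.per_element:
                    return self.per_element[key]
        return self.default


@dataclass
class Shell:
    """A contracted cartesian Gaussian shell on one center."""

    l: int
    exps: np.ndarray
    coefs: np.ndarray  # include primitive norms and contraction renormalization
    center: np.ndarray  # Bohr
    atom_index: int

    @property
    def n_functions(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def _primitive_norm(l: int, alpha: float) -> float:
    # norm of a cartesian primitive with lx = l, ly = lz = 0 (any component of
    # the shells shipped here; for l <= 1 all components share the same norm)
    from scipy.special import factorial2

    num = (2 * alpha / np.pi) ** 0.75 * (4 * alpha) ** (l / 2.0)
    den = np.sqrt(float(factorial2(2 * l - 1)) if l > 0 else 1.0)
    return num / den


def _contraction_norm(l: int, exps: np.ndarray, raw_coefs: np.ndarray) -> float:
    # self-overlap of the contracted (lx=l,0,0) function; raw_coefs already
    # include the primitive norms
    from scipy.special import factorial2

    df = float(factorial2(2 * l - 1)) if l > 0 else 1.0
    a = exps[:, None]
    b = exps[None, :]
    ov = df * (np.pi / (a + b)) ** 1.5 / (2 * (a + b)) ** l
    s = raw_coefs @ ov @ raw_coefs
    return 1.0 / np.sqrt(s)


def build_shells(molecule: Molecule, basis: BasisAssignment) -> list[Shell]:
    """Expand the basis assignment into contracted shells (centers in Bohr)."""
    shells: list[Shell] = []
    coords = molecule.coords_bohr
    for ia, sym in enumerate(molecule.symbols):
        name = basis.resolve(ia, sym).lower()
        if name not in BASIS_LIBRARY:
            raise KeyError(f"unknown basis set {name!r}; available: {sorted(BASIS_LIBRARY)}")
        table = BASIS_LIBRARY[name]
        if sym not in table:
            raise KeyError(f"basis {name!r} has no entry for element {sym!r}")
        for l, exps, coefs in table[sym]:
            e = np.asarray(exps, dtype=float)
            c = np.asarray(coefs, dtype=float)
            c = c * np.array([_primitive_norm(l, a) for a in e])
            c = c * _contraction_norm(l, e, c)
            shells.append(Shell(l, e, c, coords[ia].copy(), ia))
    return shells


def ao_labels(shells: list[Shell]) -> list[tuple[int, int, tuple[int, int, int]]]:
    """Per-AO (atom_index, l, (lx, ly, lz)) labels in shell order."""
    labels = []
    for sh in shells:
        for comp in cartesian_components(sh.l):
            labels.append((sh.atom_index, sh.l, comp))
    return labels


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian exponent triples for angular momentum l (x-major order)."""
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def aos_on_atoms(shells: list[Shell], atoms: list[int] | set[int]) -> np.ndarray:
    """Indices of AOs centered on the given atoms."""
    atoms = set(int(a) for a in atoms)
    idx = []
    k = 0
    for sh in shells:
        for _ in range(sh.n_functions):
            if sh.atom_index in atoms:
                idx.append(k)
            k += 1
    return np.array(idx, dtype=int)
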