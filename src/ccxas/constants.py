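"""Physical constants and unit conversions.

Internal units are atomic units (Hartree, Bohr); XYZ I/O is in Angstrom and
spectra are reported in eV.
"""

# CODATA 2018
HARTREE_TO_EV = 27.211386245988
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

ATOMIC_NUMBERS = {sym: z for z, sym in enumerate(ELEMENTS) if z > 0}
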