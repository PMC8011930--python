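"""Deterministic test-system roster at desk scale.

The geometries are constructed from standard bond lengths and angles (and,
for the solvated systems, hand-placed hydrogen-bonded water shells); they
are synthetic stand-ins mirroring the kinds of systems nitrogen K-edge
studies use — a methylamine chromophore with explicit water neighbours —
at a size where full CCSD is still cheap. Repeated calls return identical
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule import Molecule, load_geometry


@dataclass(frozen=True)
class Fixture:
    name: str
    xyz: str
    suggested_basis: dict
    suggested_active_atoms: tuple
    note: str

    @property
    def molecule(self) -> Molecule:
        return load_geometry(self.xyz)


def _fmt(symbols, coords, comment):
    lines = [str(len(symbols)), comment]
    for s, c in zip(symbols, coords):
        lines.append(f"{s:<2s} {c[0]:12.6f} {c[1]:12.6f} {c[2]:12.6f}")
    return "\n".join(lines) + "\n"


def _methylamine():
    """CH3-NH2 with standard bond parameters, CN axis along z."""
    rCN, rCH, rNH = 1.470, 1.090, 1.010
    sym = ["C", "N"]
    xyz = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, rCN])]
    # CH3 pointing away from N, tetrahedral
    ct, st = -1.0 / 3.0, np.sqrt(8.0) / 3.0
    for phi in (90.0, 210.0, 330.0):
        p = np.deg2rad(phi)
        sym.append("H")
        xyz.append(np.array([rCH * st * np.cos(p), rCH * st * np.sin(p), rCH * ct]))
    # NH2: N-H at 112 deg from the N->C direction, staggered w.r.t. CH3
    ct2, st2 = np.cos(np.deg2rad(112.0)), np.sin(np.deg2rad(112.0))
    for phi in (30.0, 150.0):
        p = np.deg2rad(phi)
        sym.append("H")
        xyz.append(
            np.array([rNH * st2 * np.cos(p), rNH * st2 * np.sin(p), rCN - rNH * ct2])
        )
    return sym, xyz


def _water_at(o_pos, h1_dir, h2_dir):
    """A rigid water monomer: O at o_pos, OH bonds 0.9572 A along unit dirs."""
    r = 0.9572
    o_pos = np.asarray(o_pos, float)
    h1 = o_pos + r * np.asarray(h1_dir) / np.linalg.norm(h1_dir)
    h2 = o_pos + r * np.asarray(h2_dir) / np.linalg.norm(h2_dir)
    return ["O", "H", "H"], [o_pos, h1, h2]


_WATER_SHELL = [
    # (O position, OH direction 1, OH direction 2) around methylamine;
    # the first water donates a hydrogen bond to the N lone pair
    ((0.00, -1.60, 3.60), (0.0, 0.55, -0.84), (0.94, -0.33, 0.10)),
    ((0.00, 3.10, 2.20), (-0.81, -0.55, -0.20), (0.81, -0.55, -0.20)),
    ((3.20, 0.00, 0.40), (-0.90, 0.00, 0.44), (0.55, 0.83, 0.10)),
    ((-3.20, 0.60, 0.40), (0.90, -0.10, 0.42), (-0.55, -0.83, 0.10)),
    ((0.00, -3.30, 0.00), (0.30, 0.95, 0.00), (-0.85, -0.20, 0.49)),
    ((2.40, 2.40, -1.60), (-0.70, -0.63, 0.33), (0.33, 0.63, 0.70)),
    ((-2.40, -2.40, -1.80), (0.70, 0.63, 0.33), (-0.33, -0.63, 0.70)),
    ((0.00, 0.60, -3.40), (0.00, -0.20, 0.98), (0.87, 0.30, -0.39)),
]


def _roster() -> dict[str, Fixture]:
    fx = {}
    fx["h2"] = Fixture(
        "h2",
        "2\nh2, R = 0.74 A\nH  0.000000 0.000000 0.000000\nH  0.000000 0.000000 0.740000\n",
        {"default": "sto-3g"}, (), "canonical two-electron test system",
    )
    fx["he"] = Fixture(
        "he",
        "1\nhelium atom\nHe 0.000000 0.000000 0.000000\n",
        {"default": "sto-3g"}, (), "smallest closed-shell atom",
    )
    fx["h2o"] = Fixture(
        "h2o",
        "3\nwater\nO  0.000000 0.000000 0.117300\n"
        "H  0.000000 0.757200 -0.469200\nH  0.000000 -0.757200 -0.469200\n",
        {"default": "6-31g"}, (), "single water molecule",
    )
    sym, xyz = _methylamine()
    fx["methylamine"] = Fixture(
        "methylamine", _fmt(sym, xyz, "methylamine CH3NH2"),
        {"default": "6-31g"}, (0, 1, 2, 3, 4, 5, 6),
        "nitrogen K-edge chromophore",
    )
    for n_w, name in ((2, "methylamine_w2"), (8, "methylamine_w8")):
        s_all = list(sym)
        x_all = [c.copy() for c in xyz]
        for spec in _WATER_SHELL[:n_w]:
            sw, xw = _water_at(*spec)
            s_all += sw
            x_all += xw
        fx[name] = Fixture(
            name, _fmt(s_all, x_all, f"methylamine + {n_w} water molecules"),
            # split-valence on the chromophore heavy atoms, minimal on the
            # rest — the usual bigger-basis-on-the-edge-atom compromise
            {"per_atom": {0: "6-31g", 1: "6-31g"}, "default": "sto-3g"},
            tuple(range(7)),
            "solvated chromophore; active region = methylamine",
        )
    # well-separated water dimer for locality checks
    sw1, xw1 = _water_at((0.0, 0.0, 0.0), (0.76, 0.0, 0.65), (-0.76, 0.0, 0.65))
    sw2, xw2 = _water_at((15.0, 0.0, 0.0), (0.76, 0.0, 0.65), (-0.76, 0.0, 0.65))
    fx["dimer_separated"] = Fixture(
        "dimer_separated", _fmt(sw1 + sw2, xw1 + xw2, "water dimer, 15 A separation"),
        {"default": "sto-3g"}, (0, 1, 2),
        "locality test: one active monomer",
    )
    return fx


_FIXTURES = _roster()


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def make_fixture(name: str) -> Fixture:
    """Reproducible named geometry; unknown names list the roster."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
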