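"""Shared fixtures: synthetic benzene-dimer geometries and small clusters.

The benzene dimers are idealized reconstructions of the standard
parallel-displaced and T-shaped conformers (D6h monomer, r_CC = 1.3915 A,
r_CH = 1.080 A; interplane distance 3.4 A with 1.6 A displacement, and
4.96 A centre distance, respectively), with representative aromatic
Hirshfeld volume ratios (C 0.82, H 0.60). They are synthetic stand-ins
constructed in code, not the originally published geometries.
"""

import numpy as np
import pytest

from mbdfluct.chem_io import Structure
from mbdfluct.units import ANGSTROM_TO_BOHR
from mbdfluct.vdw_params import scale_parameters

BENZENE_RCC = 1.3915  # Angstrom
BENZENE_RCH = 1.080
AROMATIC_RATIOS = {"C": 0.82, "H": 0.60}


def benzene_coords(center=(0.0, 0.0, 0.0), plane="xy"):
    """Idealized D6h benzene: 6 C then 6 H, Angstrom."""
    ang = np.pi / 3 * np.arange(6) + np.pi / 6
    carbons = np.stack(
        [BENZENE_RCC * np.cos(ang), BENZENE_RCC * np.sin(ang), np.zeros(6)], axis=1
    )
    rh = BENZENE_RCC + BENZENE_RCH
    hydrogens = np.stack(
        [rh * np.cos(ang), rh * np.sin(ang), np.zeros(6)], axis=1
    )
    coords = np.vstack([carbons, hydrogens])
    if plane == "xz":
        coords = coords[:, [0, 2, 1]]
    return coords + np.asarray(center, dtype=float)


def benzene_dimer(conformer="parallel_displaced"):
    """Two-fragment benzene dimer Structure (Bohr) + volume ratios."""
    a = benzene_coords()
    if conformer == "parallel_displaced":
        b = benzene_coords(center=(1.6, 0.0, 3.4))
    elif conformer == "t_shaped":
        b = benzene_coords(center=(0.0, 0.0, 4.96), plane="xz")
    else:
        raise ValueError(conformer)
    symbols = (["C"] * 6 + ["H"] * 6) * 2
    structure = Structure(
        symbols,
        np.vstack([a, b]) * ANGSTROM_TO_BOHR,
        np.repeat([0, 1], 12),
        comment=f"synthetic benzene dimer ({conformer})",
    )
    ratios = np.array([AROMATIC_RATIOS[s] for s in symbols])
    return structure, ratios


@pytest.fixture(scope="session")
def pd_benzene_dimer():
    return benzene_dimer("parallel_displaced")


@pytest.fixture(scope="session")
def t_benzene_dimer():
    return benzene_dimer("t_shaped")


@pytest.fixture(scope="session")
def pd_system(pd_benzene_dimer):
    structure, ratios = pd_benzene_dimer
    return structure, scale_parameters(structure, ratios)
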