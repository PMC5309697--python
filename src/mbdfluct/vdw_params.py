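"""Per-atom van der Waals parameters from Hirshfeld volume scaling.

Each atom in a molecule is modelled as a charged harmonic (Drude)
oscillator whose static polarizability alpha0, homoatomic dispersion
coefficient C6 and van der Waals radius are obtained by scaling free-atom
reference values with the Hirshfeld volume ratio v = V_eff / V_free:

    alpha0 = v * alpha0_free
    C6     = v**2 * C6_free
    R_vdw  = v**(1/3) * R_vdw_free

The characteristic (oscillation) frequency follows from the single-pole
Lorentzian closure alpha(i*w) = alpha0 / (1 + (w/omega)^2), under which the
Casimir-Polder integral C6 = (3/pi) * Int alpha(iw)^2 dw gives

    omega = (4/3) * C6 / alpha0**2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .chem_io import Structure

__all__ = [
    "FreeAtomReference",
    "PerAtomVdWParams",
    "load_free_atom_reference",
    "scale_parameters",
    "combine_c6",
    "c6_pair_matrix",
    "alpha_dynamic",
]


@dataclass(frozen=True)
class FreeAtomReference:
    """Free-atom alpha0 (Bohr^3), C6 (Ha Bohr^6), R_vdw (Bohr) per element."""

    alpha0: dict[str, float]
    c6: dict[str, float]
    rvdw: dict[str, float]

    def __contains__(self, element: str) -> bool:
        return element in self.alpha0


def load_free_atom_reference(path=None) -> FreeAtomReference:
    """Load the bundled reference table, or a user override of the same layout."""
    if path is None:
        text = (
            resources.files("mbdfluct").joinpath("data/free_atom_vdw.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    alpha0, c6, rvdw = {}, {}, {}
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line or line.startswith("element"):
            continue
        el, a, c, r = line.split()
        alpha0[el], c6[el], rvdw[el] = float(a), float(c), float(r)
        if alpha0[el] <= 0 or c6[el] <= 0 or rvdw[el] <= 0:
            raise ValueError(f"non-positive reference entry for {el}")
    return FreeAtomReference(alpha0, c6, rvdw)


@dataclass
class PerAtomVdWParams:
    """Scaled oscillator parameters per atom, aligned to the structure order."""

    alpha0: np.ndarray  # Bohr^3
    c6: np.ndarray  # Ha Bohr^6
    omega: np.ndarray  # Ha
    rvdw: np.ndarray  # Bohr

    def __post_init__(self) -> None:
        for name in ("alpha0", "c6", "omega", "rvdw"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.alpha0)

    def subset(self, indices) -> "PerAtomVdWParams":
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            alpha0=self.alpha0[indices],
            c6=self.c6[indices],
            omega=self.omega[indices],
            rvdw=self.rvdw[indices],
        )


def scale_parameters(
    structure: Structure,
    ratios: np.ndarray,
    reference: FreeAtomReference | None = None,
) -> PerAtomVdWParams:
    """Hirshfeld-volume scaling of the free-atom reference (see module docs)."""
    if reference is None:
        reference = load_free_atom_reference()
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (structure.n_atoms,):
        raise ValueError("one volume ratio per atom required")
    if np.any(ratios <= 0):
        raise ValueError("volume ratios must be positive")
    missing = sorted({s for s in structure.symbols if s not in reference})
    if missing:
        raise KeyError(f"elements missing from the free-atom reference: {missing}")
    a_free = np.array([reference.alpha0[s] for s in structure.symbols])
    c6_free = np.array([reference.c6[s] for s in structure.symbols])
    r_free = np.array([reference.rvdw[s] for s in structure.symbols])
    alpha0 = ratios * a_free
    c6 = ratios**2 * c6_free
    omega = (4.0 / 3.0) * c6 / alpha0**2
    rvdw = ratios ** (1.0 / 3.0) * r_free
    return PerAtomVdWParams(alpha0, c6, omega, rvdw)


def combine_c6(alpha0_a, c6_a, alpha0_b, c6_b):
    """Heteroatomic C6 by the harmonic-mean (TS) combination rule.

    Equivalent to the Casimir-Polder integral of two single-pole Lorentzian
    polarizabilities: C6_AB = (3/2) a1 a2 w1 w2 / (w1 + w2).
    """
    return (
        2.0
        * c6_a
        * c6_b
        / ((alpha0_b / alpha0_a) * c6_a + (alpha0_a / alpha0_b) * c6_b)
    )


def c6_pair_matrix(params: PerAtomVdWParams) -> np.ndarray:
    """All-pairs C6_AB matrix (diagonal = homoatomic C6)."""
    a = params.alpha0
    c = params.c6
    return combine_c6(a[:, None], c[:, None], a[None, :], c[None, :])


def alpha_dynamic(params: PerAtomVdWParams, freq: np.ndarray) -> np.ndarray:
    """Lorentzian alpha(i*w): shape (n_freq, n_atoms)."""
    freq = np.atleast_1d(np.asarray(freq, dtype=float))
    return params.alpha0[None, :] / (1.0 + (freq[:, None] / params.omega[None, :]) ** 2)
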