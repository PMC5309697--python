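"""Analysis of the correlated oscillator ground state.

Downstream of diagonalization: the correlated Gaussian ground-state
wavefunction gives per-atom pseudoelectron position covariances, hence
charge densities and vdW-induced density differences; the coupled
frequencies give smoothed energy spectra; and expanding the complex's
fluctuation modes in the basis of its fragments' modes gives the
collectivity measure (inverse participation of the dominant fragment
mode) and per-mode binding contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import DensityGrid, Structure
from .mbd_core import MBDSolution
from .units import ANGSTROM_TO_BOHR, EV_TO_HARTREE, HARTREE_TO_EV

__all__ = [
    "CoupledWavefunction",
    "ModeExpansion",
    "Spectrum",
    "build_wavefunction",
    "make_grid",
    "charge_density",
    "density_difference",
    "displaced_charge",
    "energy_spectrum",
    "mode_dipole_field",
    "project_modes",
    "collectivity",
    "mode_binding_contributions",
]

DEFAULT_SPACING = 0.4  # Bohr
DEFAULT_PADDING_ANGSTROM = 4.0
DEFAULT_HALF_WIDTH_EV = 0.06
DEFAULT_MODE_THRESHOLD = 0.05


@dataclass
class CoupledWavefunction:
    """Correlated Gaussian ground state of the coupled oscillators.

    Each pseudoelectron carries unit charge; its effective mass follows
    from alpha0 = q^2 / (m omega^2). ``covariance[A]`` is the 3x3 position
    covariance of pseudoelectron A about its equilibrium site.
    """

    solution: MBDSolution
    masses: np.ndarray  # (N,)
    covariance: np.ndarray  # (N, 3, 3), Bohr^2

    @property
    def n_atoms(self) -> int:
        return len(self.masses)


def pseudoelectron_masses(solution: MBDSolution) -> np.ndarray:
    """m_A = 1 / (alpha0_A omega_A^2) for unit charge."""
    return 1.0 / (solution.alpha0_atoms * solution.omega_atoms**2)


def build_wavefunction(solution: MBDSolution) -> CoupledWavefunction:
    """Ground-state covariances from the mode decomposition.

    In mass-weighted displacements, <xi xi^T> = 1/2 sum_i v_i v_i^T /
    omega~_i; atom A's position covariance is its diagonal 3x3 block
    divided by m_A.
    """
    n = solution.n_atoms
    xi_cov = (solution.modes / solution.omega_coupled[None, :]) @ solution.modes.T / 2.0
    masses = pseudoelectron_masses(solution)
    blocks = xi_cov.reshape(n, 3, n, 3)
    covariance = np.stack([blocks[a, :, a, :] / masses[a] for a in range(n)])
    return CoupledWavefunction(solution=solution, masses=masses, covariance=covariance)


def make_grid(
    structure: Structure,
    spacing: float = DEFAULT_SPACING,
    padding_angstrom: float = DEFAULT_PADDING_ANGSTROM,
) -> DensityGrid:
    """Axis-aligned regular grid enclosing all atoms with the given padding."""
    pad = padding_angstrom * ANGSTROM_TO_BOHR
    lo = structure.coords.min(axis=0) - pad
    hi = structure.coords.max(axis=0) + pad
    shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return DensityGrid(
        origin=lo,
        axes=np.eye(3) * spacing,
        shape=shape,
        values=np.zeros(shape),
    )


def charge_density(
    wavefunction: CoupledWavefunction,
    grid: DensityGrid,
    structure: Structure,
    chunk: int = 200_000,
) -> DensityGrid:
    """rho(r) = sum_A G(r; R_A, Sigma_A): one normalized anisotropic
    Gaussian of unit charge per pseudoelectron; integral = N."""
    sigma_eigs = np.linalg.eigvalsh(wavefunction.covariance)
    voxel_diag = float(np.linalg.norm(grid.axes.sum(axis=0)))
    meta = dict(grid.meta)
    if voxel_diag > np.sqrt(sigma_eigs.min()):
        meta["warning"] = (
            f"grid too coarse: voxel diagonal {voxel_diag:.3f} Bohr exceeds the "
            f"smallest wavefunction width {np.sqrt(sigma_eigs.min()):.3f} Bohr"
        )
    pts = grid.points()
    values = np.zeros(len(pts))
    for center, cov in zip(structure.coords, wavefunction.covariance):
        prec = np.linalg.inv(cov)
        norm = (2.0 * np.pi) ** (-1.5) * np.linalg.det(cov) ** (-0.5)
        for start in range(0, len(pts), chunk):
            d = pts[start : start + chunk] - center
            expo = np.einsum("mi,ij,mj->m", d, prec, d)
            values[start : start + chunk] += norm * np.exp(-0.5 * expo)
    out = grid.like(values.reshape(grid.shape))
    out.meta = meta
    return out


def density_difference(
    complex_wf: CoupledWavefunction,
    fragment_wfs: list[CoupledWavefunction],
    grid: DensityGrid,
    structure: Structure,
    fragment_atoms: list[np.ndarray],
) -> DensityGrid:
    """Delta rho = rho(complex) - sum_f rho(fragment_f) on a shared grid.

    Fragments keep their in-complex atom positions, so the difference
    isolates the polarization induced by the interfragment coupling and
    integrates to zero.
    """
    counts = sorted(int(i) for atoms in fragment_atoms for i in atoms)
    if counts != list(range(structure.n_atoms)):
        raise ValueError("fragment atom lists must partition the complex atoms")
    rho = charge_density(complex_wf, grid, structure)
    values = rho.values.copy()
    for wf, atoms in zip(fragment_wfs, fragment_atoms):
        sub = structure.subset(atoms)
        values -= charge_density(wf, grid, sub).values
    out = grid.like(values)
    out.meta = dict(rho.meta)
    return out


def displaced_charge(delta: DensityGrid) -> float:
    """Integral of the density difference over charge-accumulating voxels."""
    pos = delta.values[delta.values > 0.0]
    return float(pos.sum() * delta.voxel_volume)


@dataclass
class Spectrum:
    """Smoothed density of oscillation states on a uniform energy grid (eV)."""

    energies: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.energies))


def energy_spectrum(
    frequencies: np.ndarray,
    half_width_ev: float = DEFAULT_HALF_WIDTH_EV,
    n_points: int = 4000,
) -> Spectrum:
    """Sum of unit-area Gaussians at the coupled state energies.

    ``frequencies`` are in Hartree; the curve is on an eV axis. The
    half-width is the Gaussian half-width at half-maximum. Integral = 3N.
    """
    if half_width_ev <= 0:
        raise ValueError("half-width must be positive")
    e = np.asarray(frequencies, dtype=float) * HARTREE_TO_EV
    sigma = half_width_ev / np.sqrt(2.0 * np.log(2.0))
    grid = np.linspace(e.min() - 8 * sigma, e.max() + 8 * sigma, n_points)
    gauss = np.exp(-0.5 * ((grid[:, None] - e[None, :]) / sigma) ** 2)
    density = gauss.sum(axis=1) / (sigma * np.sqrt(2.0 * np.pi))
    return Spectrum(energies=grid, density=density)


def mode_dipole_field(
    solution: MBDSolution,
    mode_index: int,
    threshold: float = DEFAULT_MODE_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom dipole-fluctuation vectors of one coupled mode.

    Atom A's arrow is the mode's components at A scaled by q/sqrt(m_A)
    (the dipole amplitude of the mass-weighted displacement). Returns
    (vectors (N, 3), visible (N,) bool) where ``visible`` marks atoms whose
    amplitude is at least ``threshold`` times the largest one.
    """
    if not 0 <= mode_index < len(solution.omega_coupled):
        raise IndexError(f"mode index {mode_index} out of range")
    n = solution.n_atoms
    vec = solution.modes[:, mode_index].reshape(n, 3)
    vectors = vec / np.sqrt(pseudoelectron_masses(solution))[:, None]
    norms = np.linalg.norm(vectors, axis=1)
    visible = norms >= threshold * norms.max()
    return vectors, visible


@dataclass
class ModeExpansion:
    """Complex fluctuation modes expanded in the fragment-mode basis.

    ``coeffs[i, j]`` is the coefficient of embedded fragment mode j in
    coupled complex mode i. The fragment modes form a complete orthonormal
    basis of the 3N displacement space, so the matrix is orthogonal and
    every row satisfies sum_j c_ij^2 = 1.
    """

    coeffs: np.ndarray  # (3N, 3N)
    fragment_id: np.ndarray  # (3N,) fragment of basis mode j
    within_index: np.ndarray  # (3N,) index of mode j within its fragment
    fragment_omega: np.ndarray  # (3N,) coupled fragment frequency of mode j

    @property
    def n_modes(self) -> int:
        return self.coeffs.shape[0]


def project_modes(
    complex_solution: MBDSolution,
    fragment_solutions: list[MBDSolution],
    fragment_atoms: list[np.ndarray],
) -> ModeExpansion:
    """Expand each complex mode over zero-padded fragment modes."""
    n = complex_solution.n_atoms
    counts = sorted(int(i) for atoms in fragment_atoms for i in atoms)
    if counts != list(range(n)):
        raise ValueError("fragment atom lists must partition the complex atoms")
    basis = np.zeros((3 * n, 3 * n))
    frag_id = np.empty(3 * n, dtype=int)
    within = np.empty(3 * n, dtype=int)
    fomega = np.empty(3 * n)
    col = 0
    for f, (fsol, atoms) in enumerate(zip(fragment_solutions, fragment_atoms)):
        rows = np.concatenate([[3 * a, 3 * a + 1, 3 * a + 2] for a in atoms])
        nf = 3 * len(atoms)
        basis[rows[:, None], col + np.arange(nf)[None, :]] = fsol.modes
        frag_id[col : col + nf] = f
        within[col : col + nf] = np.arange(nf)
        fomega[col : col + nf] = fsol.omega_coupled
        col += nf
    coeffs = complex_solution.modes.T @ basis
    return ModeExpansion(
        coeffs=coeffs, fragment_id=frag_id, within_index=within, fragment_omega=fomega
    )


def collectivity(
    expansion: ModeExpansion, mode_index: int, convention: str = "ipr"
) -> float:
    """Collectivity of one complex mode: 1 means a single fragment mode,
    k means k equally participating fragment modes.

    ``convention="ipr"`` (default) returns 1 / max_j c_ij^2 — the inverse
    participation of the dominant fragment mode, which assigns the value 3
    to an equal three-component expansion. ``convention="linear"`` returns
    1 / max_j |c_ij| (sqrt of the former).
    """
    row = expansion.coeffs[mode_index]
    peak = float(np.max(np.abs(row)))
    if convention == "ipr":
        return 1.0 / peak**2
    if convention == "linear":
        return 1.0 / peak
    raise ValueError(f"unknown convention {convention!r}")


def mode_binding_contributions(
    complex_solution: MBDSolution, expansion: ModeExpansion
) -> np.ndarray:
    """Per-mode contribution to the interfragment MBD energy.

    Mode i contributes (1/2) (omega~_i - sum_j c_ij^2 omega_j^frag): its
    zero-point energy minus the participation-weighted fragment zero-point
    energies. Row normalization makes the contributions sum exactly to
    E_MBD(complex) - sum_f E_MBD(fragment) at fixed screened parameters.
    """
    weights = expansion.coeffs**2 @ expansion.fragment_omega
    return 0.5 * (complex_solution.omega_coupled - weights)
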