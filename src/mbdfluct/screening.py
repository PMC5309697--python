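"""Self-consistent (Dyson) screening of atomic polarizabilities.

The scaled atomic polarizabilities are dressed by the short-range part of
their mutual dipole coupling,

    B(i*w) = (A(i*w)^-1 + T_sr(i*w))^-1,

where A is the block-diagonal matrix of bare dynamic polarizabilities and
T_sr carries frequency-dependent Gaussian widths derived from alpha(i*w).
The resulting non-local polarizability matrix is contracted back to
per-atom screened parameters (row-sum over partner atoms, then one third
of the trace), and the screened C6 follows by Casimir-Polder quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import Structure
from .coupling import DEFAULT_A, DEFAULT_BETA, gaussian_width, range_separate
from .vdw_params import PerAtomVdWParams, alpha_dynamic

__all__ = [
    "imaginary_freq_grid",
    "NonlocalPolarizability",
    "ScreenedParams",
    "dyson_response",
    "solve_dyson",
    "contract_to_atoms",
    "screen_parameters",
    "interfragment_block",
]

DEFAULT_N_FREQ = 15
FREQ_SCALE = 0.5  # Ha; centre of the transformed Gauss-Legendre grid

_COMPONENTS = {"x": 0, "y": 1, "z": 2}


def imaginary_freq_grid(n: int = DEFAULT_N_FREQ, omega0: float = FREQ_SCALE):
    """Gauss-Legendre quadrature for [0, inf) via u -> omega0 (1+u)/(1-u).

    A node at w = 0 with zero weight is prepended so static quantities come
    from the same solve. Returns (nodes, weights), each length n + 1.
    """
    u, w = np.polynomial.legendre.leggauss(n)
    nodes = omega0 * (1.0 + u) / (1.0 - u)
    weights = 2.0 * omega0 * w / (1.0 - u) ** 2
    return np.concatenate(([0.0], nodes)), np.concatenate(([0.0], weights))


@dataclass
class NonlocalPolarizability:
    """B(i*w) on the frequency grid; b[0] is the static (w = 0) matrix."""

    b: np.ndarray  # (n_freq, 3N, 3N)
    freq: np.ndarray  # (n_freq,)
    weight: np.ndarray  # (n_freq,)

    @property
    def static(self) -> np.ndarray:
        return self.b[0]


@dataclass
class ScreenedParams(PerAtomVdWParams):
    """Screened per-atom parameters plus the 3x3 molecular polarizability."""

    molecular_polarizability: np.ndarray = None

    @property
    def total_alpha0(self) -> float:
        """Isotropic molecular static polarizability (trace / 3)."""
        return float(np.trace(self.molecular_polarizability) / 3.0)


def dyson_response(alpha: np.ndarray, coupling: np.ndarray) -> np.ndarray:
    """Solve B = (A^-1 + T)^-1 for per-atom isotropic polarizabilities.

    ``alpha`` has one entry per atom; ``coupling`` is any 3N x 3N symmetric
    dipole-coupling matrix. Raises if the screened system is singular.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    ainv = np.diag(np.repeat(1.0 / alpha, 3))
    m = ainv + coupling
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e14:
        s = np.linalg.svd(m, compute_uv=False)
        raise np.linalg.LinAlgError(
            f"singular screening system (smallest singular value {s[-1]:.3e}); "
            "atoms are unphysically close"
        )
    b = np.linalg.inv(m)
    return 0.5 * (b + b.T)


def solve_dyson(
    structure: Structure,
    params: PerAtomVdWParams,
    freq: np.ndarray | None = None,
    weight: np.ndarray | None = None,
    a: float = DEFAULT_A,
    beta: float = DEFAULT_BETA,
) -> NonlocalPolarizability:
    """Screen alpha(i*w) with the short-range coupling at every grid node."""
    if freq is None:
        freq, weight = imaginary_freq_grid()
    alphas = alpha_dynamic(params, freq)  # (n_freq, N)
    n = structure.n_atoms
    b = np.empty((len(freq), 3 * n, 3 * n))
    for k, alpha_w in enumerate(alphas):
        tensors = range_separate(
            structure.coords, gaussian_width(alpha_w), params.rvdw, a=a, beta=beta
        )
        try:
            b[k] = dyson_response(alpha_w, tensors.t_sr)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"Dyson screening failed at imaginary frequency {freq[k]:.4f} Ha: {exc}"
            ) from None
    return NonlocalPolarizability(b=b, freq=freq, weight=weight)


def _atom_isotropic(b: np.ndarray, n: int) -> np.ndarray:
    """Per-atom isotropic response: (1/3) tr of the row sum of 3x3 blocks."""
    blocks = b.reshape(n, 3, n, 3)
    row_sum = blocks.sum(axis=2)  # (N, 3, 3)
    return np.trace(row_sum, axis1=1, axis2=2) / 3.0


def contract_to_atoms(
    nlp: NonlocalPolarizability, structure: Structure, params: PerAtomVdWParams
) -> ScreenedParams:
    """Contract the non-local polarizability back to per-atom parameters."""
    n = structure.n_atoms
    alpha_freq = np.stack([_atom_isotropic(bk, n) for bk in nlp.b])  # (n_freq, N)
    alpha0 = alpha_freq[0]
    if np.any(alpha0 <= 0):
        bad = np.flatnonzero(alpha0 <= 0).tolist()
        raise ValueError(
            f"negative screened polarizability on atoms {bad}: geometry is in an "
            "unphysical regime"
        )
    c6 = (3.0 / np.pi) * np.einsum("k,ka->a", nlp.weight, alpha_freq**2)
    omega = (4.0 / 3.0) * c6 / alpha0**2
    rvdw = params.rvdw * (alpha0 / params.alpha0) ** (1.0 / 3.0)
    molecular = nlp.static.reshape(n, 3, n, 3).sum(axis=(0, 2))
    return ScreenedParams(
        alpha0=alpha0, c6=c6, omega=omega, rvdw=rvdw, molecular_polarizability=molecular
    )


def screen_parameters(
    structure: Structure,
    params: PerAtomVdWParams,
    n_freq: int = DEFAULT_N_FREQ,
    a: float = DEFAULT_A,
    beta: float = DEFAULT_BETA,
) -> ScreenedParams:
    """Dyson screening + contraction in one call."""
    freq, weight = imaginary_freq_grid(n_freq)
    nlp = solve_dyson(structure, params, freq, weight, a=a, beta=beta)
    return contract_to_atoms(nlp, structure, params)


def interfragment_block(
    nlp: NonlocalPolarizability,
    structure: Structure,
    frag_a: int,
    frag_b: int,
    component: str = "xy",
) -> np.ndarray:
    """Static interfragment non-local polarizability map.

    Returns the requested Cartesian component (e.g. ``"xy"``) of the atom-pair
    blocks between two distinct fragments at w = 0, as an (N_A, N_B) matrix
    suitable for heat-map rendering.
    """
    if frag_a == frag_b:
        raise ValueError("interfragment map requires two distinct fragments")
    if len(component) != 2 or any(c not in _COMPONENTS for c in component):
        raise ValueError(f"component must be two of x/y/z, got {component!r}")
    i, j = (_COMPONENTS[c] for c in component)
    atoms_a = structure.fragment_atoms(frag_a)
    atoms_b = structure.fragment_atoms(frag_b)
    blocks = nlp.static.reshape(structure.n_atoms, 3, structure.n_atoms, 3)
    return blocks[np.ix_(atoms_a, [i], atoms_b, [j])][:, 0, :, 0]
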