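"""Dipole-dipole interaction tensors with damping and finite oscillator width.

Sign convention: the 3x3 block for a pair separated by R along z is
diag(1, 1, -2) / R^3, i.e. T = (1 - 3 R^hat R^hat^T) / R^3. Short-range
coupling uses the interaction of two spherical Gaussian charge
distributions (the oscillator ground states are not point dipoles); the
long-range part uses the point-dipole form switched on by a Fermi function
of the interatomic distance relative to the damping radius
S_AB = beta * (R_vdw_A + R_vdw_B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "DipoleTensorSet",
    "bare_dipole_tensor",
    "gaussian_dipole_tensor",
    "fermi_damping",
    "range_separate",
    "long_range_tensor",
    "gaussian_width",
]

DEFAULT_A = 6.0  # Fermi steepness
DEFAULT_BETA = 0.83  # range-separation parameter (PBE-coupled value)


def gaussian_width(alpha) -> np.ndarray:
    """Drude-distribution width sigma = (sqrt(2/pi) * alpha / 3)^(1/3)."""
    return (np.sqrt(2.0 / np.pi) * np.asarray(alpha, dtype=float) / 3.0) ** (1.0 / 3.0)


@dataclass
class DipoleTensorSet:
    """Bare, short-range (Gaussian) and long-range (point) dipole tensors."""

    t_bare: np.ndarray  # (3N, 3N)
    t_sr: np.ndarray
    t_lr: np.ndarray
    a: float
    beta: float


def _pair_geometry(coords: np.ndarray):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]  # R_A - R_B
    dist = np.linalg.norm(diff, axis=-1)
    return n, diff, dist


def bare_dipole_tensor(coords: np.ndarray) -> np.ndarray:
    """Point-dipole tensor, (3N, 3N); self-blocks are zero."""
    n, diff, dist = _pair_geometry(coords)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and np.min(dist[off]) <= 1e-12:
        masked = np.where(np.eye(n, dtype=bool), np.inf, dist)
        a, b = np.unravel_index(np.argmin(masked), dist.shape)
        raise ValueError(f"coincident atoms {a} and {b}: dipole tensor diverges")
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = diff / dist[..., None]
        t = (
            np.eye(3)[None, None] - 3.0 * rhat[..., :, None] * rhat[..., None, :]
        ) / dist[..., None, None] ** 3
    t[np.eye(n, dtype=bool)] = 0.0
    return t.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def gaussian_dipole_tensor(coords: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Dipole tensor of two interacting Gaussian charge distributions.

    Obtained from the pair potential erf(R/sigma_AB)/R with
    sigma_AB = sqrt(sigma_A^2 + sigma_B^2); reduces to the bare tensor for
    R >> sigma and stays finite as R -> 0.
    """
    n, diff, dist = _pair_geometry(coords)
    widths = np.atleast_1d(np.asarray(widths, dtype=float))
    if np.any(widths <= 0):
        raise ValueError("Gaussian widths must be positive")
    sigma = np.sqrt(widths[:, None] ** 2 + widths[None, :] ** 2)
    t = np.zeros((n, n, 3, 3))
    off = ~np.eye(n, dtype=bool)
    zeta = np.zeros_like(dist)
    zeta[off] = dist[off] / sigma[off]
    pref = 2.0 * zeta / np.sqrt(np.pi) * np.exp(-(zeta**2))
    theta = erf(zeta) - pref
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = diff / dist[..., None]
        t_bare = (
            np.eye(3)[None, None] - 3.0 * rhat[..., :, None] * rhat[..., None, :]
        ) / dist[..., None, None] ** 3
        extra = (2.0 * zeta**2 * pref) / dist**3  # 4 zeta^3/sqrt(pi) e^{-z^2} / R^3
        t = (
            theta[..., None, None] * t_bare
            + extra[..., None, None] * rhat[..., :, None] * rhat[..., None, :]
        )
    # R -> 0 limit (including the excluded self blocks) is isotropic
    tiny = dist < 1e-10
    t[tiny] = 0.0
    small = tiny & off
    if np.any(small):
        iso = 4.0 / (3.0 * np.sqrt(np.pi) * sigma[small] ** 3)
        t[small] = iso[:, None, None] * np.eye(3)
    t[np.eye(n, dtype=bool)] = 0.0
    return t.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def fermi_damping(
    dist: np.ndarray, rvdw: np.ndarray, a: float = DEFAULT_A, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """Fermi switching f(R) = 1 / (1 + exp(-a (R/S_AB - 1))), zero diagonal."""
    if beta <= 0:
        raise ValueError("range-separation parameter beta must be positive")
    rvdw = np.atleast_1d(np.asarray(rvdw, dtype=float))
    s = beta * (rvdw[:, None] + rvdw[None, :])
    f = 1.0 / (1.0 + np.exp(-a * (dist / s - 1.0)))
    np.fill_diagonal(f, 0.0)
    return f


def _expand_pairs(f: np.ndarray) -> np.ndarray:
    """Per-pair scalar (N, N) -> per-component (3N, 3N)."""
    return np.kron(f, np.ones((3, 3)))


def range_separate(
    coords: np.ndarray,
    widths: np.ndarray,
    rvdw: np.ndarray,
    a: float = DEFAULT_A,
    beta: float = DEFAULT_BETA,
) -> DipoleTensorSet:
    """Split the damped dipole coupling into short- and long-range parts.

    T_lr = f * T_bare (point dipoles, used in the coupled Hamiltonian);
    T_sr = (1 - f) * T_gaussian (finite-width, used in Dyson screening).
    """
    _, _, dist = _pair_geometry(coords)
    f = _expand_pairs(fermi_damping(dist, rvdw, a, beta))
    t_bare = bare_dipole_tensor(coords)
    t_gauss = gaussian_dipole_tensor(coords, widths)
    return DipoleTensorSet(
        t_bare=t_bare, t_sr=(1.0 - f) * t_gauss, t_lr=f * t_bare, a=a, beta=beta
    )


def long_range_tensor(
    coords: np.ndarray,
    rvdw: np.ndarray,
    a: float = DEFAULT_A,
    beta: float = DEFAULT_BETA,
) -> np.ndarray:
    """Fermi-damped point-dipole tensor f * T_bare."""
    _, _, dist = _pair_geometry(coords)
    f = _expand_pairs(fermi_damping(dist, rvdw, a, beta))
    return f * bare_dipole_tensor(coords)
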