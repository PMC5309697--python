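"""Seeded synthetic geometry + volume-ratio generator.

Produces the toy systems used throughout the test-suite and examples:
oscillator dimers, linear chains, regular rings (benzene-like when N=6),
stacked ring pairs (a pi-pi toy) and random clusters with a hard
minimum-distance floor. The same spec and seed always give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import Structure

__all__ = ["FixtureSpec", "generate"]

TOPOLOGIES = ("dimer", "chain", "ring", "stacked_rings", "random_cluster")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic system (all lengths in Bohr)."""

    topology: str = "dimer"
    n_atoms: int = 2
    spacing: float = 4.0  # bond length / nearest-neighbour distance
    separation: float = 6.5  # ring-ring distance for stacked_rings
    elements: tuple[str, ...] = ("C",)
    ratio: tuple = ("constant", 1.0)  # or ("uniform", lo, hi)
    seed: int = 0
    min_distance: float = 1.8  # hard floor for random placement
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}"
            )
        if self.n_atoms < 1 or self.spacing <= 0:
            raise ValueError("need n_atoms >= 1 and positive spacing")


def _ring(n: int, bond: float, z: float = 0.0) -> np.ndarray:
    radius = bond / (2.0 * np.sin(np.pi / n))
    angles = 2.0 * np.pi * np.arange(n) / n
    return np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.full(n, z)], axis=1
    )


def _random_cluster(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    # box sized for the requested density; rejection sampling with retries
    box = spec.spacing * max(2.0, spec.n_atoms ** (1.0 / 3.0) * 1.5)
    coords = [rng.uniform(0.0, box, 3)]
    for _ in range(spec.n_atoms - 1):
        for attempt in range(spec.max_retries + 1):
            cand = rng.uniform(0.0, box, 3)
            d = np.linalg.norm(np.asarray(coords) - cand, axis=1)
            if np.min(d) >= spec.min_distance:
                coords.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_atoms} atoms at floor "
                f"{spec.min_distance} Bohr after {spec.max_retries} retries"
            )
    return np.asarray(coords)


def generate(spec: FixtureSpec) -> tuple[Structure, np.ndarray]:
    """Deterministic (Structure, volume-ratio table) for the given spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    if spec.topology == "dimer":
        n = 2
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, spec.spacing]])
        fragment_of = np.array([0, 1])
    elif spec.topology == "chain":
        coords = np.stack(
            [np.zeros(n), np.zeros(n), spec.spacing * np.arange(n)], axis=1
        )
        fragment_of = np.zeros(n, dtype=int)
    elif spec.topology == "ring":
        coords = _ring(n, spec.spacing)
        fragment_of = np.zeros(n, dtype=int)
    elif spec.topology == "stacked_rings":
        if n % 2:
            raise ValueError("stacked_rings needs an even atom count")
        half = n // 2
        coords = np.vstack(
            [_ring(half, spec.spacing, 0.0), _ring(half, spec.spacing, spec.separation)]
        )
        fragment_of = np.repeat([0, 1], half)
    else:  # random_cluster
        coords = _random_cluster(spec, rng)
        fragment_of = np.zeros(n, dtype=int)

    symbols = [spec.elements[i % len(spec.elements)] for i in range(len(coords))]
    if spec.ratio[0] == "constant":
        ratios = np.full(len(coords), float(spec.ratio[1]))
    elif spec.ratio[0] == "uniform":
        ratios = rng.uniform(float(spec.ratio[1]), float(spec.ratio[2]), len(coords))
    else:
        raise ValueError(f"unknown ratio distribution {spec.ratio[0]!r}")
    structure = Structure(
        symbols,
        coords,
        fragment_of,
        comment=f"mbdfluct fixture {spec.topology} seed={spec.seed}",
    )
    return structure, ratios
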