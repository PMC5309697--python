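"""Molecular geometry, per-atom table and volumetric-density I/O.

Geometries live in :class:`Structure` objects with coordinates in Bohr;
XYZ files are read/written in Angstrom. Fragments (the interacting
molecules of a complex) are tracked as a per-atom integer label, assigned
either explicitly as index ranges, as a single fragment, or by distance
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "Structure",
    "DensityGrid",
    "read_xyz",
    "write_xyz",
    "read_volume_ratios",
    "write_cube",
    "read_cube",
    "parse_fragment_ranges",
]

#: Atomic numbers for the elements the model parameterizes (plus a few
#: neighbours so cube files of arbitrary organic structures can be written).
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class Structure:
    """Element symbols + Cartesian coordinates (Bohr) + fragment labels.

    Fragment indices are 0-based and contiguous; every atom belongs to
    exactly one fragment. Atom order is the file order and defines atom
    identity throughout the package.
    """

    symbols: list[str]
    coords: np.ndarray  # (N, 3), Bohr
    fragment_of: np.ndarray  # (N,), int
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.fragment_of = np.asarray(self.fragment_of, dtype=int)
        n = len(self.symbols)
        if n < 1:
            raise ValueError("structure must contain at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if self.fragment_of.shape != (n,):
            raise ValueError("fragment_of must have one entry per atom")
        labels = np.unique(self.fragment_of)
        if not np.array_equal(labels, np.arange(len(labels))):
            raise ValueError(
                f"fragment indices must be contiguous from 0, got {labels}"
            )
        if n > 1:
            d = self.distance_matrix()
            iu = np.triu_indices(n, 1)
            if np.min(d[iu]) <= 0.0:
                masked = np.where(np.eye(n, dtype=bool), np.inf, d)
                a, b = np.unravel_index(np.argmin(masked), d.shape)
                raise ValueError(f"coincident atoms {a} and {b}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_fragments(self) -> int:
        return int(self.fragment_of.max()) + 1

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def fragment_atoms(self, i: int) -> np.ndarray:
        """Indices of the atoms belonging to fragment ``i``."""
        if not 0 <= i < self.n_fragments:
            raise IndexError(f"no fragment {i}")
        return np.flatnonzero(self.fragment_of == i)

    def fragments(self) -> list[np.ndarray]:
        return [self.fragment_atoms(i) for i in range(self.n_fragments)]

    def subset(self, indices: np.ndarray) -> "Structure":
        """Sub-structure of the given atoms, relabelled as one fragment."""
        indices = np.asarray(indices, dtype=int)
        return Structure(
            symbols=[self.symbols[i] for i in indices],
            coords=self.coords[indices],
            fragment_of=np.zeros(len(indices), dtype=int),
            comment=self.comment,
        )

    def with_fragments(self, fragment_of: np.ndarray) -> "Structure":
        return replace(self, fragment_of=np.asarray(fragment_of, dtype=int))

    def translated(self, shift) -> "Structure":
        return replace(self, coords=self.coords + np.asarray(shift, float))

    def rotated(self, rotation: np.ndarray) -> "Structure":
        return replace(self, coords=self.coords @ np.asarray(rotation).T)


@dataclass
class DensityGrid:
    """Scalar field on a regular 3-D grid (all lengths in Bohr)."""

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (3, 3), rows are the step vectors
    shape: tuple[int, int, int]
    values: np.ndarray  # shape == self.shape
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.shape = tuple(int(s) for s in self.shape)
        self.values = np.asarray(self.values, dtype=float)
        if abs(np.linalg.det(self.axes)) < 1e-30:
            raise ValueError("grid axis vectors are degenerate")
        if self.values.shape != self.shape:
            raise ValueError("values shape does not match grid shape")

    @property
    def voxel_volume(self) -> float:
        return abs(np.linalg.det(self.axes))

    def points(self) -> np.ndarray:
        """All grid points as an (nx*ny*nz, 3) array in C (x-major) order."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.origin + idx @ self.axes

    def integrate(self) -> float:
        return float(self.values.sum() * self.voxel_volume)

    def like(self, values: np.ndarray) -> "DensityGrid":
        return DensityGrid(self.origin, self.axes, self.shape, values)


def parse_fragment_ranges(spec: str) -> list[tuple[int, int]]:
    """Parse ``"0-11,12-23"`` into inclusive 0-based (start, stop) pairs."""
    ranges = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            ranges.append((int(lo), int(hi)))
        else:
            i = int(part)
            ranges.append((i, i))
    return ranges


def _assign_fragments(n: int, coords: np.ndarray, fragment_spec) -> np.ndarray:
    if fragment_spec is None or fragment_spec == "all":
        return np.zeros(n, dtype=int)
    if fragment_spec == "auto":
        return _cluster_fragments(coords)
    if isinstance(fragment_spec, str):
        fragment_spec = parse_fragment_ranges(fragment_spec)
    fragment_of = np.full(n, -1, dtype=int)
    for frag, (lo, hi) in enumerate(fragment_spec):
        if not (0 <= lo <= hi < n):
            raise ValueError(f"fragment range {lo}-{hi} outside 0..{n - 1}")
        if np.any(fragment_of[lo : hi + 1] >= 0):
            raise ValueError(f"fragment range {lo}-{hi} overlaps a previous range")
        fragment_of[lo : hi + 1] = frag
    if np.any(fragment_of < 0):
        missing = np.flatnonzero(fragment_of < 0)
        raise ValueError(f"atoms {missing.tolist()} not covered by any fragment range")
    return fragment_of


def _cluster_fragments(coords: np.ndarray, cutoff_angstrom: float = 2.0) -> np.ndarray:
    """Connected components of the bond graph at a distance cutoff."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    cutoff = cutoff_angstrom * ANGSTROM_TO_BOHR
    diff = coords[:, None, :] - coords[None, :, :]
    adj = (np.linalg.norm(diff, axis=-1) < cutoff).astype(int)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # relabel in order of first appearance so fragment 0 contains atom 0
    order = {lab: i for i, lab in enumerate(dict.fromkeys(labels.tolist()))}
    return np.array([order[lab] for lab in labels], dtype=int)


def read_xyz(path, fragment_spec="all") -> Structure:
    """Read a standard XYZ file (Angstrom) into a Structure (Bohr).

    ``fragment_spec`` is ``"all"`` (one fragment), ``"auto"`` (distance
    clustering at a 2.0 Angstrom cutoff), a string like ``"0-11,12-23"``,
    or a list of inclusive (start, stop) index pairs.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(
            f"{path}, line 1: expected an atom count, got {lines[0]!r}"
        ) from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}: {n} atoms declared but only {len(lines)} lines")
    comment = lines[1]
    symbols, coords = [], []
    for i, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {i}: expected 'symbol x y z', got {line!r}")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise ParseError(f"{path}, line {i}: unknown element symbol {parts[0]!r}")
        symbols.append(sym)
        coords.append([float(x) for x in parts[1:4]])
    coords = np.asarray(coords) * ANGSTROM_TO_BOHR
    fragment_of = _assign_fragments(n, coords, fragment_spec)
    return Structure(symbols, coords, fragment_of, comment=comment)


def write_xyz(structure: Structure, path) -> None:
    """Write in Angstrom; the comment line records the fragment labels."""
    coords = structure.coords * BOHR_TO_ANGSTROM
    comment = structure.comment or (
        "fragments " + " ".join(map(str, structure.fragment_of))
    )
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(structure.symbols, coords):
            fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")


def read_volume_ratios(path, structure: Structure, free_atom: bool = False) -> np.ndarray:
    """Read per-atom Hirshfeld volume ratios aligned to the structure order.

    The file is a whitespace table with one row per atom; the last column is
    the ratio (a leading index or symbol column is ignored). With
    ``free_atom=True`` (or ``path=None``) a table of ones is returned — the
    free-atom limit.
    """
    if free_atom or path is None:
        return np.ones(structure.n_atoms)
    ratios = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            ratios.append(float(line.split()[-1]))
    if len(ratios) != structure.n_atoms:
        raise ValueError(
            f"{path}: {len(ratios)} ratio rows for {structure.n_atoms} atoms"
        )
    ratios = np.asarray(ratios)
    if np.any(ratios <= 0):
        raise ValueError("volume ratios must be positive")
    return ratios


def write_cube(grid: DensityGrid, structure: Structure, path, comment: str = "") -> None:
    """Write a Gaussian cube file (Bohr, Fortran value order, 6 per line)."""
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains non-finite values")
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write((comment or "mbdfluct density") + "\n")
        fh.write("values in atomic units; outer loop x, inner loop z\n")
        fh.write(
            f"{structure.n_atoms:5d} {grid.origin[0]:12.6f} "
            f"{grid.origin[1]:12.6f} {grid.origin[2]:12.6f}\n"
        )
        for npts, ax in zip(grid.shape, grid.axes):
            fh.write(f"{npts:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}\n")
        for sym, (x, y, z) in zip(structure.symbols, structure.coords):
            zn = ATOMIC_NUMBERS[sym]
            fh.write(f"{zn:5d} {float(zn):12.6f} {x:12.6f} {y:12.6f} {z:12.6f}\n")
        flat = grid.values.reshape(nx * ny * nz)  # C order == cube order
        for start in range(0, flat.size, 6):
            chunk = flat[start : start + 6]
            fh.write(" ".join(f"{v: .12e}" for v in chunk) + "\n")


def read_cube(path) -> tuple[DensityGrid, Structure]:
    """Read a cube file written by :func:`write_cube` (orthogonal or not)."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    natoms = int(lines[2].split()[0])
    origin = np.array([float(x) for x in lines[2].split()[1:4]])
    shape, axes = [], []
    for i in range(3):
        parts = lines[3 + i].split()
        shape.append(int(parts[0]))
        axes.append([float(x) for x in parts[1:4]])
    symbols, coords = [], []
    number_to_symbol = {v: k for k, v in ATOMIC_NUMBERS.items()}
    for i in range(natoms):
        parts = lines[6 + i].split()
        symbols.append(number_to_symbol[int(parts[0])])
        coords.append([float(x) for x in parts[2:5]])
    values = np.array(
        " ".join(lines[6 + natoms :]).split(), dtype=float
    ).reshape(tuple(shape))
    structure = Structure(symbols, np.asarray(coords), np.zeros(natoms, dtype=int))
    return DensityGrid(origin, np.asarray(axes), tuple(shape), values), structure
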