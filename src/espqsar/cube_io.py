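"""Gaussian cube I/O and descriptor-table I/O.

A cube file stores a molecular geometry plus a scalar field (electron
density or electrostatic potential) on a regular, possibly skewed, lattice.
The header is: two comment lines; a line with the atom count and grid
origin; three axis lines (count + step vector each); one line per atom
(atomic number, nuclear charge, position); then the values, innermost axis
fastest.  Coordinates are bohr when the axis counts are positive and
angstrom when negative (normalised to bohr on read).  A negative atom
count flags a molecular-orbital cube, which this reader rejects.

Descriptor/activity tables are plain CSV with a required header vocabulary
``{id, activity, inv_vs_max, inv_vs_min, lumo, vs_mean, vs_plus_mean}``;
extra columns pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import BOHR_PER_ANGSTROM
from .errors import CubeFormatError, SchemaError, TableParseError, TruncationError

__all__ = [
    "Atom",
    "Molecule",
    "VolumetricGrid",
    "read_cube",
    "write_cube",
    "read_descriptor_table",
    "write_descriptor_table",
    "validate_descriptor_table",
    "REQUIRED_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class Atom:
    """A point nucleus: atomic number, nuclear charge (e) and position (bohr)."""

    atomic_number: int
    nuclear_charge: float
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.atomic_number < 1:
            raise ValueError(f"atomic_number must be >= 1, got {self.atomic_number}")
        if self.nuclear_charge <= 0:
            raise ValueError(f"nuclear_charge must be > 0, got {self.nuclear_charge}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")


@dataclass
class Molecule:
    """An ordered collection of atoms, optionally carrying a LUMO energy.

    The LUMO (lowest unoccupied molecular orbital energy) is an electronic
    descriptor supplied externally — cube files do not carry orbital
    energies — and is used untouched by the QSAR stage.
    """

    atoms: list[Atom]
    lumo: float | None = None
    compound_id: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a molecule needs at least one atom")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([a.nuclear_charge for a in self.atoms])


@dataclass
class VolumetricGrid:
    """A scalar field on a regular lattice.

    ``origin`` is the position of grid node (0,0,0); row *i* of ``axes`` is
    the step vector along grid axis *i* (bohr).  ``values[i, j, k]`` is the
    field at ``origin + i*axes[0] + j*axes[1] + k*axes[2]``.  ``field_kind``
    is ``"density"`` (e/bohr^3) or ``"potential"`` (hartree/e).
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    field_kind: str = "density"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix of step vectors")
        if abs(np.linalg.det(self.axes)) < 1e-30:
            raise ValueError("axes matrix is singular")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("values must be a 3-D array with every dimension >= 2")
        if self.field_kind not in ("density", "potential"):
            raise ValueError(f"unknown field_kind {self.field_kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume element |det(axes)| in bohr^3."""
        return float(abs(np.linalg.det(self.axes)))

    def node_coordinates(self) -> np.ndarray:
        """Physical coordinates of every grid node, shape (n1*n2*n3, 3)."""
        n1, n2, n3 = self.shape
        idx = np.indices((n1, n2, n3)).reshape(3, -1).T.astype(float)
        return self.origin + idx @ self.axes

    def min_step(self) -> float:
        return float(np.min(np.linalg.norm(self.axes, axis=1)))


# ---------------------------------------------------------------------------
# cube files


def _parse_counted_vector(line: str, lineno: int) -> tuple[int, np.ndarray]:
    parts = line.split()
    if len(parts) < 4:
        raise CubeFormatError(f"line {lineno}: expected count + 3-vector, got {line!r}")
    try:
        count = int(float(parts[0]))
        vec = np.array([float(p) for p in parts[1:4]])
    except ValueError as exc:
        raise CubeFormatError(f"line {lineno}: non-numeric field in {line!r}") from exc
    return count, vec


def read_cube(path: str | Path, field_kind: str = "density") -> tuple[Molecule, VolumetricGrid]:
    """Read a Gaussian cube file.

    Parameters
    ----------
    path
        Cube file path.
    field_kind
        What the scalar field is — ``"density"`` or ``"potential"``.  The
        format itself does not say, so the caller must.

    Returns
    -------
    (Molecule, VolumetricGrid) with geometry normalised to bohr.
    """
    text = Path(path).read_text().splitlines()
    if len(text) < 7:
        raise CubeFormatError(f"{path}: file too short for a cube header")
    natoms_line = text[2]
    natoms, origin = _parse_counted_vector(natoms_line, 3)
    if natoms < 0:
        raise CubeFormatError(
            f"line 3: negative atom count ({natoms}) flags a molecular-orbital "
            "cube, which is not supported"
        )
    if natoms == 0:
        raise CubeFormatError("line 3: cube declares zero atoms")

    counts = []
    axes = []
    angstrom = False
    for i, lineno in enumerate((4, 5, 6)):
        n, vec = _parse_counted_vector(text[lineno - 1], lineno)
        if n == 0:
            raise CubeFormatError(f"line {lineno}: zero grid points along axis {i}")
        if n < 0:
            angstrom = True
            n = -n
        counts.append(n)
        axes.append(vec)
    axes_arr = np.array(axes)

    atom_lines = text[6 : 6 + natoms]
    if len(atom_lines) < natoms:
        raise TruncationError(f"{path}: expected {natoms} atom records, found {len(atom_lines)}")
    atoms = []
    for j, line in enumerate(atom_lines):
        parts = line.split()
        if len(parts) < 5:
            raise CubeFormatError(f"atom record {j + 1}: expected 5 fields, got {line!r}")
        try:
            z = int(float(parts[0]))
            charge = float(parts[1])
            pos = np.array([float(p) for p in parts[2:5]])
        except ValueError as exc:
            raise CubeFormatError(f"atom record {j + 1}: non-numeric field in {line!r}") from exc
        atoms.append((z, charge, pos))

    scale = BOHR_PER_ANGSTROM if angstrom else 1.0
    origin = origin * scale
    axes_arr = axes_arr * scale
    atom_objs = [Atom(z, c, p * scale) for z, c, p in atoms]

    raw = " ".join(text[6 + natoms :]).split()
    expected = counts[0] * counts[1] * counts[2]
    if len(raw) != expected:
        raise TruncationError(
            f"{path}: grid declares {expected} values "
            f"({counts[0]}x{counts[1]}x{counts[2]}), found {len(raw)}"
        )
    try:
        values = np.array(raw, dtype=float).reshape(counts)
    except ValueError as exc:
        raise CubeFormatError(f"{path}: non-numeric value in data section") from exc

    mol = Molecule(atoms=atom_objs, compound_id=Path(path).stem)
    grid = VolumetricGrid(origin=origin, axes=axes_arr, values=values, field_kind=field_kind)
    return mol, grid


def write_cube(molecule: Molecule, grid: VolumetricGrid, path: str | Path) -> None:
    """Write a bohr-convention cube file readable by :func:`read_cube`.

    Floats are written with 13 significant digits so a round trip preserves
    values to better than 1e-12 relative.
    """
    n1, n2, n3 = grid.shape
    lines = [
        f"espqsar cube: {molecule.compound_id or 'unnamed'}",
        f"{grid.field_kind} on {n1}x{n2}x{n3} grid (bohr)",
        _counted_vector_line(len(molecule.atoms), grid.origin),
        _counted_vector_line(n1, grid.axes[0]),
        _counted_vector_line(n2, grid.axes[1]),
        _counted_vector_line(n3, grid.axes[2]),
    ]
    for a in molecule.atoms:
        lines.append(
            f"{a.atomic_number:5d} {a.nuclear_charge:19.12E} "
            + " ".join(f"{x:19.12E}" for x in a.position)
        )
    flat = grid.values.reshape(-1)
    for start in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:19.12E}" for v in flat[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def _counted_vector_line(count: int, vec: np.ndarray) -> str:
    return f"{count:5d} " + " ".join(f"{x:19.12E}" for x in vec)


# ---------------------------------------------------------------------------
# descriptor tables

REQUIRED_TABLE_COLUMNS = (
    "id",
    "activity",
    "inv_vs_max",
    "inv_vs_min",
    "lumo",
    "vs_mean",
    "vs_plus_mean",
)


def validate_descriptor_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the required columns exist and are numeric; return the table."""
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"descriptor table is missing columns: {missing}")
    if len(table) == 0:
        raise SchemaError("descriptor table has no rows")
    for col in REQUIRED_TABLE_COLUMNS[1:]:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"column {col!r}, row {row}: cannot parse {table[col].iloc[row]!r} as a number"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise TableParseError(f"column {col!r}, row {row}: missing value")
        table = table.assign(**{col: coerced})
    return table


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited descriptor/activity table (header-driven, CSV)."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty descriptor table") from exc
    return validate_descriptor_table(table)


def write_descriptor_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_descriptor_table(table).to_csv(path, index=False)
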