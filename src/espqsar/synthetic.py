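"""Synthetic test inputs with closed-form oracles.

Two generators:

* Gaussian-atom molecules — the electron density is a superposition of
  spherical Gaussians  rho(r) = A * exp(-alpha * |r - c|^2)  with point
  nuclei at the centers.  Everything downstream then has a closed form:
  the electron count is N = A * (pi/alpha)^{3/2}, the isodensity surface
  of a single atom is a sphere of radius sqrt(ln(A/iso)/alpha), and the
  potential at distance r is Z/r - N*erf(sqrt(alpha)*r)/r.  These stand in
  for real quantum-chemical densities in every surface/ESP test.

* Linear-model QSAR tables — descriptor columns drawn from per-column
  normal distributions, response = intercept + X beta + N(0, noise_sd),
  for regression parameter-recovery tests.

One integer seed governs all stochastic generation (default 20130415).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .constants import DEFAULT_ISOVALUE
from .cube_io import Atom, Molecule, VolumetricGrid
from .errors import BoundaryLeakError, SingularityError

__all__ = [
    "DEFAULT_SEED",
    "GaussianAtomSpec",
    "SyntheticQsarSpec",
    "make_gaussian_molecule",
    "analytic_isosurface_radius",
    "analytic_esp",
    "make_qsar_table",
    "neutral_atom_spec",
    "cation_like_spec",
    "anion_like_spec",
]

DEFAULT_SEED = 20130415


@dataclass(frozen=True)
class GaussianAtomSpec:
    """One spherical-Gaussian 'atom': nuclear charge Z, density A*exp(-alpha r^2)."""

    Z: float
    A: float
    alpha: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.A <= 0 or self.alpha <= 0:
            raise ValueError("A and alpha must be > 0")
        if self.Z <= 0:
            raise ValueError("Z must be > 0")

    @property
    def n_electrons(self) -> float:
        """Integrated electron count N = A (pi/alpha)^{3/2}."""
        return self.A * (math.pi / self.alpha) ** 1.5


def neutral_atom_spec() -> GaussianAtomSpec:
    """Z = N: the surface potential is small and constant — the benchmark fixture."""
    spec = GaussianAtomSpec(Z=math.pi**1.5, A=1.0, alpha=1.0)
    return spec


def cation_like_spec() -> GaussianAtomSpec:
    """Z > N: positive potential over the whole surface (empty negative patch)."""
    return GaussianAtomSpec(Z=1.25 * math.pi**1.5, A=1.0, alpha=1.0)


def anion_like_spec() -> GaussianAtomSpec:
    """Z < N: negative potential over the whole surface (empty positive patch)."""
    return GaussianAtomSpec(Z=0.75 * math.pi**1.5, A=1.0, alpha=1.0)


def make_gaussian_molecule(
    specs: list[GaussianAtomSpec],
    grid_spacing: float = 0.15,
    padding: float = 5.0,
    strict: bool = True,
) -> tuple[Molecule, VolumetricGrid]:
    """Evaluate the Gaussian superposition on an axis-aligned grid.

    The grid spans the atom centers plus ``padding`` on every side.  If the
    boundary density exceeds 1e-6 of the default isovalue the grid leaks
    density: a warning, or :class:`BoundaryLeakError` when ``strict``.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    centers = np.array([s.center for s in specs], dtype=float)
    lo = centers.min(axis=0) - padding
    hi = centers.max(axis=0) + padding
    axes_1d = [np.arange(lo[d], hi[d] + 0.5 * grid_spacing, grid_spacing) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes_1d, indexing="ij")
    rho = np.zeros_like(X)
    for s in specs:
        r2 = (X - s.center[0]) ** 2 + (Y - s.center[1]) ** 2 + (Z - s.center[2]) ** 2
        rho += s.A * np.exp(-s.alpha * r2)

    boundary_max = max(
        rho[0].max(), rho[-1].max(), rho[:, 0].max(), rho[:, -1].max(),
        rho[:, :, 0].max(), rho[:, :, -1].max(),
    )
    if boundary_max > 1e-6 * DEFAULT_ISOVALUE:
        msg = (
            f"boundary density {boundary_max:.3e} e/bohr^3 exceeds "
            f"{1e-6 * DEFAULT_ISOVALUE:.1e}; increase padding"
        )
        if strict:
            raise BoundaryLeakError(msg)
        warnings.warn(msg, stacklevel=2)

    atoms = [
        Atom(atomic_number=max(1, round(s.Z)), nuclear_charge=s.Z, position=np.array(s.center))
        for s in specs
    ]
    grid = VolumetricGrid(
        origin=np.array([a[0] for a in axes_1d]),
        axes=np.diag([grid_spacing] * 3),
        values=rho,
        field_kind="density",
    )
    return Molecule(atoms=atoms, compound_id="gaussian-synthetic"), grid


def analytic_isosurface_radius(spec: GaussianAtomSpec, isovalue: float = DEFAULT_ISOVALUE) -> float:
    """Exact isodensity radius sqrt(ln(A/isovalue)/alpha) of a single Gaussian atom."""
    if isovalue >= spec.A:
        raise ValueError(f"isovalue {isovalue} >= peak density {spec.A}: no surface")
    if isovalue <= 0:
        raise ValueError("isovalue must be > 0")
    return math.sqrt(math.log(spec.A / isovalue) / spec.alpha)


def analytic_esp(spec: GaussianAtomSpec, r: float) -> float:
    """Exact potential (hartree/e) of a Gaussian atom at distance r from its center.

    Z/r - N*erf(sqrt(alpha)*r)/r, the point nucleus plus the screened
    Gaussian electron cloud.
    """
    if r <= 0:
        raise SingularityError("analytic_esp requires r > 0")
    N = spec.n_electrons
    return spec.Z / r - N * erf(math.sqrt(spec.alpha) * r) / r


@dataclass
class SyntheticQsarSpec:
    """A known linear model for generating descriptor/activity tables."""

    n_rows: int
    coefficients: dict[str, float]
    intercept: float = 0.0
    predictor_distributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_rows <= len(self.coefficients) + 1:
            raise ValueError("n_rows must exceed the number of coefficients + 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_qsar_table(spec: SyntheticQsarSpec) -> pd.DataFrame:
    """Draw predictors, apply the linear model, add Gaussian noise.

    Reproducible: the same spec (including seed) yields an identical table.
    """
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, np.ndarray] = {}
    for name in spec.coefficients:
        mean, sd = spec.predictor_distributions.get(name, (0.0, 1.0))
        cols[name] = rng.normal(mean, sd, size=spec.n_rows)
    y = spec.intercept + sum(spec.coefficients[k] * cols[k] for k in spec.coefficients)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_rows)
    table = pd.DataFrame({"id": np.arange(1, spec.n_rows + 1), **cols, "activity": y})
    return table
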