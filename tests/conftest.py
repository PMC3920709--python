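import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import espqsar as eq

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    """The packaged 15-compound descriptor/activity table."""
    return eq.load_table1()


@pytest.fixture(scope="session")
def neutral_system():
    """Neutral Gaussian atom (Z = N) on a 0.12-bohr grid: the benchmark fixture."""
    spec = eq.neutral_atom_spec()
    mol, grid = eq.make_gaussian_molecule([spec], grid_spacing=0.12, padding=5.0)
    return spec, mol, grid


@pytest.fixture(scope="session")
def neutral_sampled_surface(neutral_system):
    """The neutral atom's isosurface with potentials on 300 area-weighted samples."""
    spec, mol, grid = neutral_system
    surface = eq.extract_isosurface(grid)
    surface = eq.subsample_surface(surface, 300, seed=1)
    source = eq.EspSource.from_density(grid)
    return spec, eq.sample_potential_on_surface(surface, source, mol)


@pytest.fixture(scope="session")
def coarse_gaussian_system():
    """Single Gaussian cloud (A=1, alpha=1) on a fast 0.25-bohr grid, no nucleus needed."""
    spec = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0)
    mol, grid = eq.make_gaussian_molecule([spec], grid_spacing=0.25, padding=5.0)
    return spec, mol, grid


@pytest.fixture()
def rng():
    return np.random.default_rng(20130415)
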