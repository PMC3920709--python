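"""Isosurface extraction, trilinear interpolation, surface potential sampling."""

import math

import numpy as np
import pytest
from scipy.special import erf

import espqsar as eq
from espqsar.errors import EmptySurfaceError, ExtrapolationError


def _sphere_area(r):
    return 4.0 * math.pi * r**2


def test_gaussian_atom_surface_is_sphere_of_closed_form_radius():
    """0.001-contour of A exp(-alpha r^2) is a sphere of radius sqrt(ln(A/iso)/alpha)."""
    spec = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0)
    _, grid = eq.make_gaussian_molecule([spec], grid_spacing=0.15, padding=5.0)
    surf = eq.extract_isosurface(grid, 0.001)
    r0 = eq.analytic_isosurface_radius(spec, 0.001)
    assert r0 == pytest.approx(math.sqrt(math.log(1000.0)), rel=1e-12)
    assert surf.total_area == pytest.approx(_sphere_area(r0), rel=0.02)
    radii = np.linalg.norm(surf.sample_points, axis=1)
    assert radii == pytest.approx(r0, rel=0.02)


def test_mesh_area_converges_with_grid_spacing():
    """Halving the spacing shrinks the area error by about the expected order."""
    spec = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0)
    exact = _sphere_area(eq.analytic_isosurface_radius(spec))
    errs = []
    for h in (0.4, 0.2):
        _, grid = eq.make_gaussian_molecule([spec], grid_spacing=h, padding=5.0)
        surf = eq.extract_isosurface(grid)
        errs.append(abs(surf.total_area - exact) / exact)
    assert errs[1] < errs[0]
    order = math.log(errs[0] / errs[1]) / math.log(2.0)
    assert order > 1.0


def test_constant_grid_below_isovalue_is_empty_surface():
    grid = eq.VolumetricGrid(
        origin=np.zeros(3), axes=np.diag([1.0] * 3), values=np.full((4, 4, 4), 1e-6)
    )
    with pytest.raises(EmptySurfaceError):
        eq.extract_isosurface(grid, 0.001)


def test_nonpositive_isovalue_rejected(coarse_gaussian_system):
    _, _, grid = coarse_gaussian_system
    with pytest.raises(ValueError):
        eq.extract_isosurface(grid, 0.0)


def test_two_separated_atoms_double_the_area():
    spec1 = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0, center=(-5.0, 0, 0))
    spec2 = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0, center=(5.0, 0, 0))
    _, grid = eq.make_gaussian_molecule([spec1, spec2], grid_spacing=0.15, padding=5.0)
    surf = eq.extract_isosurface(grid)
    single = _sphere_area(eq.analytic_isosurface_radius(spec1))
    assert surf.total_area == pytest.approx(2 * single, rel=0.02)


def test_vertices_sit_on_the_isodensity_contour():
    """Interpolated density at every mesh vertex is the isovalue within the MC bound."""
    spec = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0)
    _, grid = eq.make_gaussian_molecule([spec], grid_spacing=0.15, padding=5.0)
    surf = eq.extract_isosurface(grid, 0.001)
    dens = eq.trilinear_interpolate(grid, surf.vertices)
    np.testing.assert_allclose(dens, 0.001, atol=0.001 * 0.05)


def test_translation_equivariance():
    shift = np.array([0.6, -0.35, 0.2])
    spec0 = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0)
    spec1 = eq.GaussianAtomSpec(Z=1.0, A=1.0, alpha=1.0, center=tuple(shift))
    _, g0 = eq.make_gaussian_molecule([spec0], grid_spacing=0.3, padding=5.0)
    _, g1_shifted_frame = eq.make_gaussian_molecule([spec1], grid_spacing=0.3, padding=5.0)
    # same lattice relative to the atom because the box is centered on it
    s0 = eq.extract_isosurface(g0)
    s1 = eq.extract_isosurface(g1_shifted_frame)
    np.testing.assert_allclose(s1.vertices - shift, s0.vertices, atol=1e-9)
    np.testing.assert_allclose(s1.sample_weights, s0.sample_weights, rtol=1e-9)


# ---------------------------------------------------------------------------
# trilinear interpolation


def _linear_field_grid():
    ax = np.linspace(0, 2, 5)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = 2 * X + 3 * Y - Z
    return eq.VolumetricGrid(
        origin=np.zeros(3), axes=np.diag([ax[1]] * 3), values=vals, field_kind="density"
    )


def test_trilinear_exact_on_linear_field(rng):
    grid = _linear_field_grid()
    pts = rng.uniform(0.05, 1.95, size=(10, 3))
    got = eq.trilinear_interpolate(grid, pts)
    expect = 2 * pts[:, 0] + 3 * pts[:, 1] - pts[:, 2]
    np.testing.assert_allclose(got, expect, rtol=1e-12, atol=1e-12)


def test_trilinear_exact_at_grid_nodes():
    grid = _linear_field_grid()
    corner = grid.origin + np.array([1, 2, 3]) @ grid.axes
    got = eq.trilinear_interpolate(grid, corner[None, :])
    assert got[0] == pytest.approx(grid.values[1, 2, 3], abs=1e-13)


def test_trilinear_outside_box_raises():
    grid = _linear_field_grid()
    with pytest.raises(ExtrapolationError):
        eq.trilinear_interpolate(grid, np.array([[5.0, 0.1, 0.1]]))


def test_trilinear_second_order_convergence(rng):
    """Error on a smooth Gaussian field drops at measured order >= 1.8 when h halves."""
    pts = rng.uniform(-0.8, 0.8, size=(40, 3))
    exact = np.exp(-np.sum(pts**2, axis=1))
    errs = []
    for h in (0.2, 0.1):
        ax = np.arange(-1.5, 1.5 + h / 2, h)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = np.exp(-(X**2 + Y**2 + Z**2))
        grid = eq.VolumetricGrid(np.array([ax[0]] * 3), np.diag([h] * 3), vals)
        errs.append(np.abs(eq.trilinear_interpolate(grid, pts) - exact).mean())
    order = math.log(errs[0] / errs[1]) / math.log(2.0)
    assert order >= 1.8


# ---------------------------------------------------------------------------
# potential sampling on the surface


def test_neutral_atom_surface_potential_constant_and_matches_erf(neutral_sampled_surface):
    """Z = N Gaussian atom: V on the isosurface sphere is constant and equals
    (Z - N erf(sqrt(a) r0))/r0, converted to kcal/mol, within 2%."""
    spec, surface = neutral_sampled_surface
    v = surface.sample_potentials
    w = surface.sample_weights
    mean = float((w * v).sum() / w.sum())
    spread = math.sqrt(float((w * (v - mean) ** 2).sum() / w.sum())) / abs(mean)
    assert spread < 0.02
    r0 = eq.analytic_isosurface_radius(spec)
    exact = eq.analytic_esp(spec, r0) * eq.HARTREE_TO_KCAL_PER_MOL
    assert mean == pytest.approx(exact, rel=0.02)


def test_zero_source_gives_zero_potentials():
    grid = eq.VolumetricGrid(
        origin=np.array([-2.0] * 3), axes=np.diag([1.0] * 3), values=np.zeros((5, 5, 5))
    )
    tri = eq.TriangulatedSurface(
        vertices=np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]),
        triangles=np.array([[0, 1, 2]]),
        sample_points=np.array([[1 / 3, 1 / 3, 0.0]]),
        sample_weights=np.array([0.5]),
    )
    out = eq.sample_potential_on_surface(tri, eq.EspSource.from_density(grid), None)
    np.testing.assert_array_equal(out.sample_potentials, 0.0)


def test_subsample_preserves_weighted_mean_approximately(neutral_sampled_surface):
    _, surface = neutral_sampled_surface
    sub = eq.subsample_surface(surface, 100, seed=3)
    assert sub.n_samples == 100
    w_mean_full = np.average(surface.sample_potentials, weights=surface.sample_weights)
    w_mean_sub = np.average(sub.sample_potentials, weights=sub.sample_weights)
    assert w_mean_sub == pytest.approx(w_mean_full, rel=0.02)
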