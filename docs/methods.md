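# Methods

## The pipeline

For each molecule the package goes cube → surface → potential → statistics
→ regression:

1. **Input** — a Gaussian cube file carrying the electron density ρ on a
   regular (possibly skewed) lattice in bohr, plus the nuclei (atomic
   number, nuclear charge, position) in the header. The LUMO energy is not
   part of the cube format and is joined from a sidecar CSV (`id, lumo`).
2. **Surface** — the ρ = 0.001 e/bohr³ isodensity contour, extracted by
   marching cubes and mapped through the grid's affine frame.
3. **Potential** — V(r) = Σ Z_A/|R_A − r| − ∫ρ(r′)/|r′−r| dr′ evaluated at
   the surface sample points; a precomputed potential grid can be supplied
   instead, in which case it is trilinearly interpolated.
4. **Statistics** — extrema, patch means, Π, σ² components and ν, converted
   once from hartree to kcal/mol (627.5095).
5. **Regression** — OLS of activity on descriptor columns, with stepwise
   selection or a fixed nested entry order.

## Units

All geometry is bohr, density e/bohr³, potential hartree/e internally. The
single hartree→kcal/mol conversion happens when potentials land on the
surface, so no quantity can be double-scaled. Angstrom-convention cube
files (negative axis counts) are converted on read; molecular-orbital
cubes (negative atom count) are rejected.

## Surface extraction

scikit-image's marching cubes (Lewiner tables, linear edge interpolation)
runs in index space; vertices map through `origin + idx @ axes`. Each
triangle contributes one sample at its centroid with its area as quadrature
weight — pairing every potential sample with a natural weight for the
surface integrals. Degenerate (zero-area) triangles are dropped. Ambiguous
saddle cells resolve by the library's convention; the descriptor statistics
are insensitive to this at the tolerances used here.

The isovalue is configurable (`--isovalue`, default 0.001 e/bohr³ — the
Bader convention) for sensitivity checks.

On the closed-form fixture (single Gaussian density, isosurface an exact
sphere) the mesh area converges at roughly second order in the grid
spacing and is within 2% of 4πr₀² at 0.15 bohr.

## Coulomb integral quadrature

The density integral uses a midpoint voxel sum with the voxel volume from
|det(axes)|. Far from the query point this is accurate to ~10⁻⁵ relative
at 0.25-bohr spacing. Near the query point the bare 1/d kernel is noisy,
which matters for *neutral* systems where the nuclear and electronic terms
cancel to a small residual: the surface potential of the neutral Gaussian
atom is ~4×10⁻⁴ hartree against component magnitudes of ~2 hartree. Two
refinements control this:

- voxels whose center lies within 3 (minimum) grid steps of the query
  point are subdivided 3×3×3 with constant density;
- each subvoxel interacts through the potential of a uniform sphere of
  equal volume — identical to 1/d outside the sphere radius and finite at
  contact — which regularises the kernel without an ad-hoc cutoff.

Convergence (neutral Gaussian atom, surface mean vs the exact
(Z − N·erf(√α r₀))/r₀): 2.6% at h = 0.15 bohr, 0.4% at h = 0.12, 0.3% at
h = 0.10; the area-weighted coefficient of variation of the (analytically
constant) surface potential is ~1% at h = 0.12. The test suite and
examples therefore use 0.12 bohr for quantitative neutral-atom checks and
coarser grids where only the electronic term (no cancellation) is probed.
"Constancy" of a surface potential is always measured as the area-weighted
std/|mean|, because max−min on a marching-cubes mesh is dominated by a few
centroid outliers.

Because potential evaluation is the expensive stage (cost ∝ samples ×
voxels), the pipeline can subsample the surface to `max_esp_samples`
area-weighted samples (seeded); the statistics are weighted means, so a
uniform random subset estimates them without bias. The default examples
use 300 samples of ~18 000 centroids, which leaves the subsampling error
well below the quadrature error.

## Surface statistics

Averages are **area-weighted** by default. The classical formulas are
plain point averages; those depend on mesh density, so they are offered as
`weighting="uniform"` for comparison, while the area-weighted forms are
the physically well-posed default. Definitions:

- Π = Σw|V−⟨V_s⟩| / Σw, centred on the full-surface mean;
- σ²₊ is the variance of the positive-patch samples about ⟨V_s⁺⟩, σ²₋
  about ⟨V_s⁻⟩ (the standard Politzer centring), σ²_tot = σ²₊ + σ²₋;
- ν = σ²₊σ²₋/(σ²_tot)², set to 0 when σ²_tot = 0; the algebraic bound
  ν ≤ 1/4 holds with equality iff σ²₊ = σ²₋;
- samples with V = 0 count as positive (measure-zero tie rule);
- an empty patch has no mean (reported as absent/NaN) and variance 0.

Surface extrema are taken over the mesh samples, not a continuous
optimisation; at the grid spacings above this is within the stated
tolerances on the closed-form fixtures.

## QSAR stage

`fit_ols` delegates the solve to statsmodels (QR-based OLS with intercept)
and reports R², adjusted R² = 1−(1−R²)(n−1)/(n−p−1), residual standard
error √(SSres/(n−p−1)) and coefficient standard errors. Rank deficiency
raises a collinearity error naming the dependent columns; n ≤ p+1 raises a
degrees-of-freedom error.

Stepwise selection uses partial-F probabilities (the squared t of a
candidate's coefficient in the augmented model): smallest-p candidate
enters while p < 0.05, included predictors with p > 0.10 leave, ties break
by input order. On the packaged 15-compound table no single descriptor
passes p < 0.05 alone (the best single-descriptor R² is 0.054), so the
default stepwise run selects nothing; the five-descriptor model is
reproduced through `nested_model_trace`, which fits the prefix models of a
given entry order directly. The response (IC₅₀, mmol/dm³) is regressed
untransformed — consistent with the packaged equation reproducing the
packaged predicted-activity column to ±0.002.

## Synthetic data

The generator emulates two things and only two things:

- **Gaussian-atom densities** ρ(r) = A·e^{−α|r−c|²} with point nuclei —
  chosen because every downstream stage then has a closed form (electron
  count N = A(π/α)^{3/2}, isosurface radius √(ln(A/iso)/α), potential
  Z/r − N·erf(√α r)/r). Defaults A = 1 e/bohr³, α = 1 bohr⁻² give an
  atom-sized surface (r₀ = 2.63 bohr) and N ≈ 5.57 electrons; neutral,
  cation-like (Z = 1.25N) and anion-like (Z = 0.75N) variants exercise
  full, empty-negative and empty-positive surface partitions. These are
  *not* molecular densities: no shell structure, no anisotropy, no
  multi-centre interference — so passing tests demonstrate the numerics of
  the pipeline, not chemical realism.
- **Linear-model tables** with independent normal predictor columns and
  Gaussian response noise, for parameter-recovery and selection tests.
  Note that independent draws at given column moments carry more signal
  variance than the strongly correlated real descriptor columns; the
  population R² of such a generator is S/(S+σ²) with S = Σβ²σ_x², which
  for the packaged table's moments and σ = 0.095 is ≈ 0.98, above the
  real series' 0.922.

One integer seed (default 20130415) governs all stochastic generation;
generation is bit-reproducible for a fixed seed.

## Numerical edge rules

- Query points within 1e-8 bohr of a nucleus raise a singularity error.
- Grids that do not straddle the isovalue raise an empty-surface error;
  isovalue ≤ 0 is a domain error.
- Synthetic grids whose boundary density exceeds 10⁻⁶ of the default
  isovalue raise (strict mode) or warn — the box leaks density.
- Trilinear interpolation outside the lattice raises rather than
  extrapolates.

## Problem sizes

Quantitative surface checks run on single-atom fixtures at 0.10–0.15 bohr
spacing (~10⁵–10⁶ voxels, ~2×10⁴ triangles, 300 potential samples);
regression checks use the 15-row packaged table and synthetic tables up to
n = 200. These sizes put every closed-form comparison comfortably inside
its tolerance while keeping the full suite interactive.

## Known limitations

- The ESP engine is a direct sum (no multipole acceleration, no periodic
  boundary conditions); cost grows as samples × voxels.
- Surface extrema from mesh samples slightly under-estimate true continuous
  extrema on coarse meshes.
- Real quantum-chemical densities for the packaged compound series are out
  of scope; the published-number checks flow through the packaged printed
  descriptor table, and the surface engine is validated on analytic
  fixtures instead.
- The stepwise path on n = 15 with correlated descriptors is fragile by
  nature; the nested-trace interface is the reproducible route to a known
  entry order.
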