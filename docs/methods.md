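# Methods

This note records the model, the numerical choices, and the design
decisions behind `qdma`, at the level of detail a maintainer or a
careful user needs.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Distributed multipole analysis

A molecular charge density in a Gaussian basis is a sum of nuclear
point charges and products of primitive Gaussians.  By the Gaussian
product theorem, the product of primitives with exponents α, β centered
at **A**, **B** is a polynomial times a single Gaussian at the overlap
center **P** = (α**A** + β**B**)/(α + β); its multipole expansion about
**P** *terminates* at rank l_A + l_B.  The engine:

1. enumerates every primitive pair, computes its exact multipole series
   about **P** (closed-form 1D even Gaussian moments; no quadrature);
2. assigns the series to the expansion site minimizing the
   radius-scaled distance |**P** − **s**|/r_s, translates it there with
   the regular-solid-harmonic addition theorem, and accumulates;
3. adds each nuclear charge as a rank-0 term on its nearest site.

The defining exactness property — site series translated to any common
origin and summed reproduce the direct analytic molecular moments at
every retained rank — is tested at 1e-8 (analytic path) and 1e-6 (grid
path) on every bundled density.

Conventions: real spherical components throughout, Racah-normalized
regular solid harmonics (R₀₀ = 1, R₁₀ = z, R₂₀ = (3z² − r²)/2), so a
rank-l component is in e·a₀^l.  Geometry is handled in Ångström with
a₀ = 0.529177 Å; all moments are atomic units.  Shell angular momentum
up to g (l = 4) is supported, Cartesian or pure (spherical) d and
higher; the formatted-checkpoint AO ordering is used (Cartesian d:
xx, yy, zz, xy, xz, yz; pure: m = 0, +1, −1, +2, −2).  Contraction
coefficients multiply primitives normalized to the axial Cartesian
component; pure components are unit-normalized solid-harmonic
Gaussians.

### Allocation details

* **Site radii.** All sites default to radius 1.0 (dimensionless
  scale); a per-element table can override.  Radii enter only through
  ratios.
* **Exact ties.** Overlap centers of symmetry-equivalent pairs sit
  exactly on bisector planes (e.g. every C–C bond midpoint in benzene).
  Contributions tied within 1e-9 relative scaled distance are split
  equally among the tied sites.  With a winner-takes-all rule the
  per-site series of a symmetric molecule would change under rigid
  rotation (floating-point noise picks different winners), breaking the
  rotational invariance of the descriptors; equal splitting restores
  it.  The single-point query `assign_site` keeps the documented
  lowest-index tie-break.
* **Diffuse density (grid path).** Nearest-site allocation of very
  diffuse primitive pairs is unstable — a tiny exponent change moves
  charge wholesale between sites.  Pairs with combined exponent below
  `exponent_switch` (default 4.0 a.u., recorded in output metadata) are
  therefore integrated on an atom-centered Becke-weighted molecular
  grid, and each point's charge is divided between sites with *smooth*
  fuzzy-cell weights (Becke cell functions over the sites, three
  sharpening iterations, with Becke's size adjustment when radii
  differ).  Smooth division — rather than hard nearest-site points — is
  how established DMA implementations treat pointwise density, and it
  matters: for a planar molecule every analytic overlap center lies in
  the plane, so a hard Voronoi cell hands an off-plane probe site a
  discontinuous, overweighted slab of diffuse density.  The hard
  assignment remains available (`grid_partition="nearest"`).
* **Grid.** Radial: Gauss–Legendre mapped through r = r_m(1+x)/(1−x)
  with per-element r_m (0.8 Bohr for H, 1.2–1.4 for C/N/O); angular:
  Gauss–Legendre × uniform φ product grid.  Default resolution
  (n_rad, n_θ, n_φ) = (80, 32, 64) is the smallest meeting the 1e-6
  totals-equality oracle on the bundled diffuse-augmented benzene
  density; the binding constraint is angular, because the sharpened
  Becke cell functions vary rapidly on a sphere.  Setting
  `exponent_switch = 0` reproduces the analytic path bitwise.

## Aromaticity descriptors

The molecule is first oriented: ring centroid to the origin, best-fit
ring-plane normal (smallest principal direction of the ring
coordinates) to +z, first ring atom fixing +x.  Re-orienting a
wavefunction conjugates the density matrix with the per-shell rotation
of the AO components, so a density computed in any frame can be
analyzed.  Orientation diagnostics (RMS out-of-plane deviation, normal
vector) are carried into the descriptor records.

The expansion sites for descriptor runs are **the atoms plus the single
probe site at (0, 0, 1 Å)** — one extra point per run:

* `q2zz_ring`, `q2mag_ring`: sums of the per-site Q₂₀ / |**Q**₂| over
  the ring-atom sites, untranslated.
* `q2zz_origin`, `q2mag_origin`: Q₂₀ and |**Q**₂| of the *total* series
  referred to (0, 0, 0).  For a neutral molecule with vanishing dipole
  this total is origin-independent and independent of the partition.
  An alternative reading — summing per-atom |**Q**₂| magnitudes after
  translating each site series to the origin — is exposed as
  `origin_reading="atom-sum"` for sensitivity checks (the two differ
  because the norm is nonlinear; the default is the total-series
  reading).
* `q2zz_probe`, `q2mag_probe`: the probe site's own allocation.

No *empty* expansion site is placed at the ring center.  In a regular
hexagon the meta-chord midpoints are exactly equidistant from the ring
center and the nearest carbon, so a center site competing for density
makes the ring-atom descriptors discontinuous functions of the
geometry right at the symmetric reference — the worst possible place
for a benzene-normalized index.  A punch file that does carry an origin
site is still accepted; its series simply joins the translated total.

Normalization is signed elementwise division by the reference (benzene)
raw values; zero reference components flag the entry undefined (NaN)
rather than dropping it.  The z-scan reuses one density decomposition
and re-allocates with atoms + one probe per height; the default height
list is 0, 0.5, 0.529 (= a₀), 1, 1.5, …, 4.5 Å.

## Fixture densities and the SCF backend

The analysis pipeline consumes densities; it never computes them.  For
reproducible offline tests the package bundles small fchk documents
generated by `qdma.scf`, a deliberately minimal closed-shell RHF
(McMurchie–Davidson integrals, DIIS) with unrelaxed (response-free) MP2
one-particle densities.  Basis sets are the published STO-3G, 6-31G and
6-311G families with standard diffuse/polarization exponents, embedded
in full in each document.  Study conditions, chosen once:

* **CO₂**: MP2/6-311+G(2d) on the linear experimental geometry
  R(C–O) = 1.162 Å.  A triple-zeta basis with diffuse functions and
  double polarization is the smallest class that gives reliable
  molecular quadrupoles; the density is the unrelaxed MP2 one (the
  backend has no Z-vector response).
* **Benzene z-scan**: MP2 in 6-31G augmented with one diffuse p shell
  (exponent 0.0438) on each carbon — a scaled-down diffuse-augmented
  double-zeta basis; the diffuse p functions carry the far π density
  the probe site samples.
* **Bond-alternation (T1) series**: HF/STO-3G at ΔR = 0, 0.05, 0.1,
  0.15, 0.2 Å, one fixed level of theory across the series, analytic
  allocation path.

What the generated fixtures emulate — and what they do not: they are
genuine self-consistent densities of the real molecules, so allocation,
translation and descriptor behavior is exercised on realistic density
matrices; but the small bases underestimate absolute quadrupoles
(minimal-basis benzene's |Θ_zz| is roughly a third of the converged
value), so tests assert structure (exactness, symmetry, monotone
trends, sign patterns, the z-scan argmax), not absolute agreement with
converged calculations.  Trends on the distortion families use this
package's documented displacement conventions (`benchmark_fixtures`),
not any external benchmark's optimized geometries.

## Benchmark geometry conventions

Benzene: D6h, R(C–C) = 1.39 Å (the equalized aromatic bond length),
R(C–H) = 1.09 Å, built from sign-symmetric literals so symmetry-
equivalent bonds are bitwise equal and the bond-alternation measure of
the reference is exactly zero.  Distortions (parameter 0 returns the
base geometry unchanged):

* **T1** ΔR: ring bonds alternate 1.39 ∓ ΔR/2 (planar, D3h, centroid
  preserved, C–H along the C–C–C bisector); valid for ΔR < 0.4 Å.
* **T2** α: each C–H rotated in-plane by α, alternating sense.
* **T3** α: boat — the para pair C1/C4 (with hydrogens) lifted so the
  centroid→carbon direction makes angle α with the plane.
* **T4** α: chair — alternating ±z displacement by the same rule.
* **T5** α: C–H wag — hydrogens tilted out of plane by α, alternating,
  carbons fixed.

CO₂ and other linear molecules are built on the z-axis with the center
of mass at the origin.

## Numerical policy and limitations

* Algebraic identities are tested at 1e-10 absolute, integral-level
  comparisons at 1e-8, grid-path totals at 1e-6 (double-precision
  contraction over ≤10⁴ primitive pairs; grid quadrature).
* Translation is exact for terminating series; punch round-trips hold
  to 1e-12, limited to 10 significant digits by the punch format.
* The engine accepts any symmetric matrix as a "density"; electron
  count is validated against Tr(DS) when requested, not enforced.
* Closed shells only in the backend; charged even-electron species
  (e.g. aromatic cations) are supported by the engine itself, which
  never assumes neutrality.
* Per-site values depend on the allocation conventions above and will
  differ from other DMA programs' site values even when every
  recombined total agrees; the punch reader exists so that output of an
  external DMA program can be fed directly into the descriptor layer
  when bit-compatibility with that program matters.
* Ring perception is not attempted: ring atoms are user-specified
  indices, also for polycyclic local analyses.
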