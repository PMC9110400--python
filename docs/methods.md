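# Methods

This note documents the models, numerical choices and known limitations of
`coralmech`, in the order the pipeline runs.

## Tensor algebra

All fourth-order tensor computation uses the orthonormal (Mandel) 6-vector
basis, in which matrix products equal double contractions and matrix
inversion equals tensor inversion; the engineering Voigt convention exists
only at the I/O boundary. This removes the factor-of-2 bookkeeping that
plagues stiffness algebra in mixed conventions. Rotations follow intrinsic
Z–Y–Z Euler angles (φ about z, θ about the new y, ψ about the new z), so the
crystal 3-axis maps onto the needle direction n(φ,θ) = (sinθ cosφ,
sinθ sinφ, cosθ) and the sinθ dθ dφ measure of the orientation average is
natural. The 6×6 rotation operator is assembled exactly from the images of
the six Mandel basis dyads, and is verified in the tests against a
brute-force 3×3×3×3 Bond transformation.

Isotropic projection is orthogonal in the Frobenius inner product:
3k = ⟨C, J⟩ and 2μ = ⟨C, K⟩/5 with J, K the volumetric/deviatoric
projectors. Engineering constants follow from E = 9kμ/(3k+μ) and
ν = (3k−2μ)/(2(3k+μ)).

## Crystal input and transverse isotropy

The crystal input is the median of published experimental stiffnesses for
orthorhombic aragonite (9 constants, GPa). Because the needles are modelled
as transversely isotropic about the growth (c) axis, the orthorhombic
median is symmetrised by arithmetic means of the paired constants:
C11′ = C22′ = ½(C11+C22), C13′ = C23′ = ½(C31+C23), C44′ = C55′ =
½(C44+C55), with C12 and C33 kept and the in-plane closure
C66′ = ½(C11′−C12′). Averaging is an interpretation: the source formulas
for this step are printed with ambiguous indices and minus signs that do
not yield a positive-definite tensor if taken literally, so the package
uses the averaging reading and verifies positive definiteness. The result
(C11′ = 140.6, C33 = 85.0, C12 = 60.3, C13′ = 14.75, C44′ = 33.45,
C66′ = 40.15 GPa) is slightly softer in norm than the raw median, as
expected of a symmetrisation.

## Self-consistent polycrystal (pristine wall)

Each needle, and each spherical nano-pore, is embedded in the yet-unknown
effective medium — the natural scheme for a polycrystal with no matrix
phase. Parameters and defaults:

- aspect ratio a = 10 (long/short axis of the needle, unitless) — the
  morphologically supported choice for CWC aragonite fibres;
- nano-porosity φ_np = 0.039, treated as spherical voids because the
  organic filling contributes no stiffness;
- convergence: relative Frobenius change < 1e-8, max 200 iterations,
  initial guess = isotropic projection of the Voigt orientation mean.

The effective medium is isotropised by projection every iteration, which
makes the closed-form isotropic-matrix Eshelby tensors exact within the
scheme; a random-orientation needle assembly does produce isotropic
behaviour, and the converged tensor is isotropic by construction. Eshelby
tensors use the classical prolate-spheroid closed forms (symmetry axis e3,
callers rotate) with a guard switching to the sphere branch for
|a−1| < 1e-6; they are validated against a numerical Green-operator
quadrature over the unit sphere and against the infinite-cylinder limit.

Orientation quadrature is Gauss–Legendre in cosθ (64 nodes) × uniform
azimuth (8 nodes). The azimuth nodes are redundant once the matrix is
isotropic but are kept as a consistency check; halving or doubling the grid
moves E_poly by far less than 0.2% (tested). Needle spin ψ is fixed to 0 —
irrelevant for a transversely isotropic crystal.

With the median crystal this yields E_poly = 87.3 GPa, ν_poly = 0.227 at
φ_np = 3.9%. This sits between the dense-crystal Reuss and Voigt
orientation bounds (92.2 and 98.0 GPa) after void softening, and scales
exactly linearly with the crystal stiffness. It is substantially stiffer
than nanoindentation-derived values for real skeletons (45–67 GPa), which
reflect additional compliance sources the two-phase model does not carry;
see Limitations.

## Mori–Tanaka acidification damage

Dissolution pores measured in skeletons exposed to acidified water are
near-spheroidal (mean axis ratio ≈ 1.9) with random orientations, which
justifies a spherical-void Mori–Tanaka scheme on top of the converged
polycrystal. The void limit is implemented exactly (pore stiffness zero)
rather than by a small-stiffness surrogate. The scheme is monotone in the
Löwner order, matches the scalar k/μ void formulas to 1e-9, agrees with the
self-consistent estimate to <1% at dilute porosity, and removes 50.0% of
the Young's modulus at φ_OA = 0.333. The intrinsic φ_np and the
acidification φ_OA are distinct quantities and are never merged: the
baseline strengths and stiffness already embed φ_np.

## Strength upscaling

The stress concentration tensor 𝔹(0,θ) maps macroscopic stress to the
average stress of a needle at polar angle θ (azimuth 0 by axisymmetry of
uniaxial loading). Its bracketed normaliser reuses the same orientation
average and nano-pore term as the elasticity scheme with φ = φ_np; the
mean-field mixture rule (1−φ_np)⟨𝔹⟩ = 𝕀 holds to 1e-10 and the whole
object is cross-checked against an independent full-tensor oracle.

Failure search: tractions σ_nn = n·σ·n and σ_nt = n·σ·t with the tangent t
spun by ψ about n; g(θ,ψ) = σ_nn + β|σ_nt| maximised on the stated grid
Δθ = π/128, Δψ = π/32 for tension (Ŝ = e3⊗e3) and compression (−e3⊗e3),
then polished by a bounded 1-D refinement around the grid argmax (removes
grid bias without changing the criterion). Strengths are reported as
positive magnitudes, compression negative internally. Ties across symmetry
orbits report the smallest θ. The strength is homogeneous of degree one in
the interfacial pair, so the compressive/tensile ratio depends only on β.

With the averaging TI crystal the tensile branch reproduces the published
polycrystal values to 0.5%; the compressive branch computes ≈ 20% below
the published figure under every reading of the printed procedure we
tested (alternative concentration-tensor layouts, lateral-interface
criteria, alternative TI symmetrisations, evaluation at the
tension-critical orientation, grid variations). The compression landscape
is smooth with a single mirrored maximum, so the difference is not an
optimiser artifact. The corresponding acceptance checks are deliberately
left failing rather than adjusted.

## Quadric yield surface

From the uniaxial pair: cohesion h = ⅔ σ_ut σ_uc/(σ_uc−σ_ut) (MPa) and
friction coefficient T = √6 (σ_uc−σ_ut)/(σ_uc+σ_ut) (unitless). At
φ_OA = 0 the criterion is the cone ‖dev 𝐒‖ = T(h − σ_m): Y+1 is positively
homogeneous on it, the origin gives Y = −1, and solving Y = 0 along ±e3⊗e3
returns the input strengths to 1e-6 (round-trip property). For φ_OA > 0 the
(1−φ) and φ factors close the surface and shrink it monotonically; uniaxial
strengths at any porosity are extracted by bracketed root finding along the
loading ray.

## Material point

A strain-driven elastic-predictor / return-mapping integrator with
associative flow on the quadric surface. Rate dependence is a Perzyna
overstress dκ/dt = ⟨Y⟩^m/η with m = 1 and η = 0 by default: the
rate-independent limit is what all quantitative checks use, and the viscous
branch is a documented regularisation (the original finite-element
material's viscous law is not public, so no viscous parameter here is
calibrated). The coupled (σ, Δλ) system is solved by a scaled hybrid-Newton;
stress states that cannot return to the smooth cone fall back to a purely
volumetric apex return at 𝐒 = h𝐈 (φ_OA = 0 only; closed surfaces have no
apex). Return-mapped states satisfy |Y| < 1e-8; plastic dissipation is
non-negative step by step (convex surface, associative flow). The uniaxial
driver iterates the two equal lateral strain increments to zero lateral
stress with a bracketed scalar solve per step; its plateau reproduces the
yield-surface strength to machine precision and its unloading slope is the
elastic modulus.

## Branch fragility surrogate

A hollow circular Euler–Bernoulli cantilever stands in for a coral branch:
drag line load w = ½ ρ C_d D v² (ρ = 1027 kg/m³, C_d = 1.0 for a cylinder —
configurable, since only the current speed is physically constrained),
δ_tip = wL⁴/8EI, root bending stress σ = MR/I, hydrostatic pressure
superposed as a mean stress. Failure is read from the yield surface as a
utilisation (Y+1 at the extreme fibre; ≥ 1 fails), inverted for the
critical current speed by root finding with an infinite sentinel below the
speed cap. Porosity is applied through the whole wall (the critical
stresses concentrate at the outer periphery, where the damage actually is)
and erosion thins the outer radius only. Default geometry (5 mm outer
radius, 1.2 mm wall, 80 mm length) is configuration, not data. The
compliance grid over porosity × thinning is monotone in both axes; the
published colony-scale flexibility numbers belong to an image-based
finite-element model and are out of this surrogate's scope.

## Image analysis and phantoms

Conventions: solid = 1, isotropic voxels in µm, (z, y, x) indexing;
6-connectivity for the background fill and 26-connectivity for pores (the
complementary pairing avoiding topological paradoxes). Porosity is
conservative: enclosed pore volume over (pore + solid) volume in the VOI,
with exterior space removed by a border fill.

The affected layer is extracted per slice as the alpha shape (Delaunay
triangles with circumradius < 1/α; α = 0.05 in 1/voxel units, an
interpretation documented here because the source procedure omits the
scale) of pore-voxel centroids, dilated by half a voxel to account for
voxel extent; radial thickness is sampled as 2 × the Euclidean distance
transform on the medial axis of that region. The factor 2 (half-width to
width) is fixed by the phantom round-trip. Geometry caution: structures
with enclosed 2-D holes of radius below 1/α voxels (20 at the default) get
their holes absorbed into the alpha shape; phantom bores are kept larger.

Pore shape: per 26-connected component, ellipsoid semi-axes from the
coordinate covariance (cov = diag(semi²)/5 for a uniform ellipsoid, plus
the 1/12-voxel self-moment), degree of anisotropy = major/minor axis.
Touching pores merge — documented connectivity semantics.

Outer-wall thinning works in-plane per slice (matching erosion applied to
upsampled CT cross-sections): border-connected 2-D background after a
closing defines the outer contour; solid within the given depth of it is
removed, leaving bore and pore surfaces untouched. Depths exceeding the
wall perforate it with a warning. On clean synthetic geometry this
fill+closing contour equals what a geodesic active contour would find; on
noisy grey-value reconstructions it is a simplification.

**Phantom generator.** Hollow-cylinder wall along z with randomly oriented
spheroidal pores (axis ratio ~ N(1.9, 0.3), clipped at 1) confined to a
peripheral band of the requested depth; pores are carved clipped to the
band mask, which keeps the radial pore-density profile uniform with sharp
edges and every pore enclosed (1-voxel protective shells at the outer
surface and z faces). Carving proceeds until the in-band porosity reaches
the target; the ground truth records the exact pore list, the realised
in-band porosity and the realised radial band depth. Defaults emulate the
dissolution fabric reported for acidified skeletons: in-layer porosities
10–35%, layer depth ~110–250 µm, a ~450 µm outer radius and ~200 µm wall at
10 µm voxels. A `block` geometry with a central cubic VOI covers the
uniform-porosity case (the worked 28%-in-120 µm configuration). What the
phantoms do not emulate: grey-value noise, partial-volume surfaces,
open-to-surface dissolution pits, bioerosion traces — so passing
round-trips validate the estimators on clean binary data, not robustness
to segmentation error.

Quantitative round-trip tests use a dense small-pore configuration
(33% in-band porosity, 10 µm minor radius at 10 µm voxels) so that slice
sections cover the band well; at realistic sparser configurations the
slice-wise alpha shape reads the layer systematically thinner (a
density-coverage effect of the estimator, visible in its ~4% residual even
when dense).

## Problem sizes

Default problem sizes throughout were chosen as the smallest that leave the
quantitative contracts comfortably converged: 512-node orientation grids
for homogenization (grid-doubling moves E_poly by <1e-10 relative), the
stated π/128 × π/32 strength grid (doubling moves strengths by <0.5%),
80–120 step material-point ramps, and phantoms of ~10⁶ voxels.

## Known limitations

- The two-phase (crystal + void) elasticity model overpredicts the
  stiffness of real skeletal walls measured by indentation; intercrystal
  organic interfaces and hierarchical porosity are not represented.
- The compressive strength branch does not reproduce the published table
  value (analysis above); downstream defaults therefore take the published
  baseline strengths as inputs where the published chain is wanted.
- Rate-dependent parameters are placeholders; only the rate-independent
  limit is verified.
- The beam surrogate ignores vortex shedding, added mass, self-weight and
  geometric taper; it ranks damage states rather than predicting absolute
  colony failure.
- Image metrics assume clean binary input; thresholding and reconstruction
  artifacts of real scans are out of scope.
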