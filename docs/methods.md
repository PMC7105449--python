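# Methods

`afcomp` models the human annulus fibrosus (AF) as a fiber-reinforced
composite and reproduces a multiscale workflow: constitutive laws are fixed
at the sub-tissue scale (extrafibrillar matrix, collagen fiber bundles),
specimens are assembled from lamellae, and bulk mechanics are predicted by
virtual mechanical tests and compared against tissue-testing literature.

## Constitutive model

**Extrafibrillar matrix** — compressible neo-Hookean solid,

    W = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2,

with Lamé constants from (E_matrix, nu_matrix) = (0.22 MPa, 0.3).  The
(ln J)^2 coefficient is lam/2, which is the form whose small-strain limit is
exactly the isotropic (E, nu) elasticity tensor; this is verified by a
finite-difference Hessian test.

**Ground substance of fiber bundles / homogenized tissue** — Holmes–Mow
solid, W = c/2 (e^Q − 1) with

    Q = beta/(lam+2mu) [ (2mu−lam)(I1−3) + lam(I2−3) − (lam+2mu) ln(J²) ],
    c = (lam+2mu)/(2 beta),

which reduces to the same (E, nu) tangent at the identity for any beta
(tested for beta in {0.5, 1, 3.3}).  beta = 1 throughout.

**Collagen fibers** — tension-only power-linear family with stretch
λ_n = |F a₀|: zero below λ_n = 1, a toe region up to the transition stretch
λ₀, and a linear region with tangent modulus E_lin beyond.  The default
convention writes the toe energy in powers of (λ_n² − 1),

    psi_toe = xi (λ_n² − 1)^gamma,
    xi = E_lin / (4 gamma (gamma−1)) (λ₀² − 1)^(2−gamma),

and continues past λ₀ with

    psi_lin = psi_toe(λ₀) + t₀ (λ_n − λ₀) + E_lin/2 (λ_n − λ₀)²,
    t₀ = 2 gamma xi λ₀ (λ₀² − 1)^(gamma−1),

so the fiber nominal stress t = d psi/d λ_n is continuous at λ₀ and its
tangent in the linear region is exactly E_lin.  A strict-literal branch
algebra (powers of (λ_n − 1) with the quadratic coefficient
B = E_lin/2 [(λ₀²−1)/(2(gamma−1)) + λ₀²]) is available as
`convention="literal"` for comparison; it is energy- but not
stress-continuous, which is why the transition-continuous convention is the
default.

**Osmotic swelling** — ideal Donnan equilibrium.  The fixed charge density
dilutes with swelling through solid-volume kinematics,
cF(J) = cF₀ (1 − φ₀)/(J − φ₀) (configurable to stay at cF₀), and the
swelling pressure

    Δπ = φ_osm R T ( sqrt(cF² + 4 c_ext²) − 2 c_ext )

is subtracted (times identity) from the elastic stress of charge-carrying
constituents.  cF₀ = −100 mmol/L for the matrix, 0 for fibers (they do not
swell actively); φ_osm = 0.927 applies symmetrically to both phases;
bath 0.15 M, T = 298 K.  Transient transport is out of scope: the
strain-dependent Holmes–Mow permeability k(J) = k₀ ((J−φ₀)/(1−φ₀))^alpha
exp(M (J²−1)/2) and the ion diffusivities are housed as parameters and
exposed (k₀ = 0.0064 mm⁴/(N s), φ₀ = 0.3, alpha = 2, M = 4.8) but only the
swelling *equilibrium* enters the mechanics.

**Units** are fixed to mm / N / MPa / mmol/L / s.

## Microstructure

Each lamella is 0.2 mm thick with one row of full-length cylindrical fiber
bundles (radius 0.06 mm) on its mid-plane, in-plane center-to-center pitch
0.22 mm, oriented ±30° to the transverse (circumferential) plane with the
sign alternating between lamellae.  This yields an analytic bundle volume
fraction Vf = pi r²/(pitch · thickness) ≈ 0.257.  The pitch is read as
center-to-center ("edge" convention available): the edge-to-edge reading
gives Vf ≈ 0.17, implausibly low against AF histology.

Two model families:

* **SEP** (separate volumes): bundles and matrix are distinct materials.
  The voxelizer assigns every voxel the exact volume fraction of bundle it
  contains (sub-cell sampling, fraction exact to <3%), and a majority label
  for inspection/export; on the laminate path each lamella is a ply whose
  material is the Voigt mixture (1−Vf)·matrix + Vf·bundle.
* **HOM** (homogenized): every point carries the Holmes–Mow ground plus
  BOTH fiber families, each weighted Vf/2 (a single lamella: one family at
  Vf).  The weighting is the volume-consistent homogenization of the SEP
  description; with the calibrated parameter sets the SEP and HOM
  single-lamella responses coincide to ~3 digits, which matches the
  near-identical calibrations the two families are supposed to share.

## Solvers

* **Material point** — mixed stretch/stress control on the nine components
  of F, Newton iteration with finite-difference Jacobian, prescribed-stress
  residual below 1e−8 MPa per increment.
* **Free swelling** — symmetric-F Newton solve of sigma = 0 with osmotic
  pressure ramped in sub-steps; returns the swollen reference from which
  engineering strain is measured.
* **Laminate** — plies share the in-plane deformation; each ply relaxes its
  through-thickness F column so out-of-plane Cauchy components vanish; bulk
  stress is the thickness-weighted ply average.  Used for biaxial and
  single/multi-lamella homogeneous-response questions.
* **Voxel FE** — total-Lagrangian trilinear hexahedra on the voxel map
  (anisotropic voxel edges supported).  Residuals use closed-form Cauchy
  stresses (a numba kernel on the hot path, bit-checked against the
  vectorized numpy reference); the element tangent is a central finite
  difference of the element residual (h = 2e−6), so fibers, osmotic terms
  and boundary effects share one consistent code path.  Newton reuses the
  sparse LU factorization while the residual contracts and refactorizes
  near the tolerance; convergence criterion ||r_free||₂ < 1e−6 ||r||₂.
  Load stepping: 20 equal increments to the target strain with adaptive
  halving and a linear-extrapolation predictor.  An F-bar
  (centroid-dilatation) variant is available (`fbar=True`) but off by
  default: at nu = 0.3 volumetric locking is minor, and the dilatation
  coupling destabilizes Newton at clamped-grip corners under large shear.
  A patch test (affine Dirichlet data on a heterogeneous-mesh homogeneous
  material) reproduces the uniform deformation to 1e−10.

Boundary conditions: *gripped* and *vertebrae-attached* hold all (or, in
the guided variant, only the loading) displacement components of the end
faces after free swelling; *parallel-plate* bonds the z faces and
translates the top plate tangentially.  Nominal stress is the grip reaction
over the post-swelling cross-section; strain is engineering strain from the
swollen configuration.

## Protocols and calibration

Virtual tests: uniaxial tension to 20% engineering strain, biaxial tension
(ratios 1:1 and 1:0, stopped at 15%), simple shear to 10%.  Moduli are
least-squares slopes: toe over the first 10% of the strain range, linear
over the last 25%; region moduli E_low/E_med/E_high are tangents where the
stress reaches 10/50/90% of its peak.  A curve is labeled nonlinear (NL)
when linear/toe > 3, else pseudo-linear (PL).

Single-lamella calibration loads the lamella along the fiber direction to
5% engineering strain — the sub-failure range of single-lamella
experiments, inside which the toe–linear transition is traversed — without
a swelling pre-step (the two-step swell-then-load protocol describes the
multi-lamellar validation tests).  `calibrate` runs bounded least squares
on log-scaled {E_matrix, E_lin, gamma, λ₀} (beta and nu fixed) against the
three region moduli, accepting when all are within 10%.

A known limitation, documented deliberately: the three experimental region
moduli (5.96/32.5/77.6 MPa) have tangent ratios that grow *faster than
linearly* with stress (ratio 5.45 over a 5× stress interval).  A
homogeneous material point of this constitutive family is bounded by
tangent ∝ sigma^((gamma−2)/(gamma−1)) ≈ sigma^0.8 (fibers) and
∝ sigma^1.0 (exponential ground), so no parameter set reproduces that
triple at a material point; the published calibration evidently reflects
specimen-scale inhomogeneity in the original large-mesh models.
`calibrate` therefore converges to the best-achievable moduli and reports
the residuals honestly.  Self-consistency (targets generated by the model
itself) is recovered to ~1e−10.

## Validation harness

Study means/SDs ship as a packaged CSV.  Pooling uses the sample-weighted
mean and the standard pooled-variance SD, sqrt(Σ(nᵢ−1)SDᵢ²/(Σnᵢ−s)) — the
form that reproduces the published pooled values (0.67 ± 0.57 axial
gripped; 20.11 ± 11.25 axial vertebrae-attached); the literal printed
formula is available as an option.  Thirteen validation cases are encoded:
circumferential gripped linear vs four studies, axial gripped vs two, axial
vertebrae-attached vs two, three biaxial representative-curve cases
(relative band, default ±30%, exclusive at the boundary), and two
parallel-plate shear cases.  The pass rule is |prediction − mean| ≤ 1 SD
(boundary inclusive).  Feeding the harness the published SEP and HOM
predictions returns 10/13 and 1/13 — the published pass counts.

## Geometry study

The sweep runs gripped circumferential uniaxial FE models over lengths
6–15 mm and widths 2–3 mm (the full grid is 10 × 5 = 50 geometries; the
desk-scale default in the tests is a 4 × 3 sub-grid with the same corner
points) and fits

    log10(E) = b0 + b1 log10(L) + b2 (1/W) + b3 AR

with backward elimination at p ≤ 0.05, then the LMG decomposition (mean
sequential R² increment over all regressor orderings, normalized to 100%).
Exact coefficient values depend on the source discretization and are not
reproduction targets; the sign pattern, the monotone trends, and the
AR > 4 plateau are.

## Problem sizes and defaults

The published models used 0.5–1M tetrahedra; this package's defaults are
chosen for a workstation: voxel edge 0.2 mm (one voxel per lamella
thickness; bundle content preserved exactly by partial-volume weights),
3-lamella specimens 10 × 2.5 mm (gripped strips) and 4 × 15 mm
(vertebrae-attached wall segment, an anatomically motivated choice — disc
height by anterior-wall arc — since the source geometry is not given),
20 load increments.  A through-thickness refinement to 0.1 mm changes the
vertebrae-attached linear modulus by 2.5%, so that case is treated as
converged at the reported precision.  The circumferential multi-lamellar
response is more resolution-sensitive: refining the through-thickness edge
(0.2 → 0.1 → 0.05 mm) resolves the matrix-rich inter-lamellar gaps, which
shear-decouples adjacent ±30° lamellae and softens the stack substantially
(e.g. a 6 × 2 mm three-lamella specimen: 35 → 24 → 13 MPa).  The published
large-mesh models carry this decoupling intrinsically; at the desk-scale
default the stack is over-coupled, so circumferential moduli run stiff and
the thickness-convergence property (3/4/5 lamellae within 5%) is only
approached, not reached, under refinement (consecutive spreads
24% → 10% → 8%/4%).  All shipped numbers state the resolution they were
computed at.

## What the virtual specimens do and do not capture

The voxel SEP model carries the bundle volume fraction exactly and the
bundle *placement* only at voxel resolution, so inter-bundle shear-lag is
under-resolved at the default edge; fiber dispersion, radial fibers,
cross-links, fiber–matrix sliding and rate dependence are not modelled
(deliberately, matching the source model's assumptions).  Consequences
visible in the shipped numbers: toe moduli run soft relative to experiments
(engagement is more abrupt than in real tissue), the circumferential linear
modulus lands inside the experimental 1-SD band, and the vertebrae-attached
axial modulus lands ~16% below its pooled band.
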