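# Methods

This note documents the statistical model, the numerical choices, and
the design decisions behind `ontotraj`, together with what the synthetic
tests do and do not establish about real data.

## Shape space and superimposition

A specimen is an ordered set of k 3D landmarks; flattened vectors are
landmark-major (x1, y1, z1, x2, …) throughout, and every downstream
object (residual covariance Se, coefficients β, contrasts) inherits that
convention. Centroid size is the square root of the summed squared
deviations from the centroid. GPA centres all configurations, optionally
scales them to unit centroid size, and alternates rotation-to-consensus
with re-averaging until the consensus RMS change falls below 1e-10
(double-precision plateau) or 100 iterations, which is an error. The
summed squared distance to the consensus is non-increasing across
iterations because each step solves its subproblem exactly. Reflections
are disallowed by default in all superimpositions — landmark
correspondences are biologically homologous — with a flag to allow them.

Tangent coordinates are the orthogonal projection onto the plane at the
unit-norm consensus direction c: t = (I − cc′)vec(x). The orthogonal
(rather than stereographic) projection is the standard choice for the
small shape variation these analyses assume. Euclidean distances in the
tangent plane agree with Procrustes distances to first order; tests
verify the agreement at 1e-4 relative error for small perturbations.

## Thin-plate splines and semilandmark sliding

The 3D TPS kernel is U(r) = −r; with this sign the bending-energy matrix
(the landmark block of the inverted bordered kernel system) is positive
semi-definite with the affine maps as its exact null space, both
verified numerically in the tests. Coincident landmarks make the system
singular; the error names the offending pair and suggests a ridge term
(disabled by default, λ = 1e-8 recommended when needed).

Semilandmarks slide along one tangent direction (curves: normalized
central differences of neighbouring curve points, one-sided at curve
ends) or a tangent plane (surfaces: orthogonal complement of the mesh
vertex normal when a mesh is given, else of the best-fit-plane normal of
the 6 nearest patch points). The tangent step minimizes the bending
energy of the TPS from a reference onto the specimen over all stacked
tangent displacements in closed form (generalized least squares), so the
energy after the step never exceeds the energy before; back-projection
(nearest point on the specimen mesh, or on the piecewise-linear curve
when no mesh exists) can raise it again, and both values are logged.
The reference defaults to the GPA consensus recomputed at each of 3
outer iterations (convergence is typically complete by 2–3); a fixed
template mode is available. A Procrustes-distance sliding criterion is
deliberately not implemented — bending energy is the criterion this
package commits to. Surface points without a mesh are slid but not
back-projected, with a warning.

## Shape model and inference

The species x age model uses cell-means coding: X holds one indicator
column per cell (species alphabetical, ages ascending — a deterministic
column order), and the marginal-mean contrast L is the identity, hence
square and invertible. That invertibility is required later by the
transport update β^tr = L⁻¹ẑ^tr, and is the reason treatment coding was
rejected. OLS is applied column-wise; Se = E′E/(n − q).

RRPP tests nested models by permuting the rows of the *reduced*-model
residuals (not the raw data), adding them back to the reduced fitted
values, and recomputing an F-like statistic from the drop in residual
Procrustes sum of squares; p-values use the +1 convention and are never
zero. The same scheme, with the additive species + age model (common
trajectory) as the reduced model, builds the null for the pairwise
trajectory tests on path distance, average direction and trajectory
shape. An exhaustive-enumeration mode (n ≤ 8) exists for exact checks.
Every stochastic operation takes a mandatory-by-convention seed that is
recorded in the output tables and provenance record.

The allometric model fits tangent shape on log centroid size with
species-specific intercepts and slopes; the regression score projects
centred shapes onto the unit-norm common slope of the pooled
within-species regression. Per-species slopes and scores are also
returned, since species are usually displayed separately.

## Parallel transport

Trajectories are compared after moving them to a common start: the
consensus (GPA without scaling) of the first-stage expected marginal
means. The default `linear_shift` mode applies each species' first-stage
superimposition to all its stage means and then translates the whole
trajectory so it starts exactly at the reference — the Euclidean
(linear-shift) approximation of parallel transport. Growth vectors are
invariant to the final translation. A second mode, `opa_per_stage`,
superimposes each stage mean independently; the two readings are not
operationally identical, so the mode is recorded in every output. The
Euclidean approximation degrades with large variation; if any stage mean
deviates from the reference by more than 0.3 of its norm, a warning is
raised. Specimens are transported as transported cell mean + original
tangent residual, so within-cell covariance and Se are preserved exactly
(identities tested at 1e-10). Whether the per-stage superimposition
should scale is genuinely open; scaling is disabled for consistency with
the unscaled reference GPA.

## Growth-vector statistics

Growth vectors are differences of consecutive transported stage means,
v̂ = (L_j − L_{j−1})β^tr; magnitude is the Euclidean norm (Procrustes
units), rate is magnitude per day of the interval, path distance the sum
of step magnitudes. Angles are arccosines of clamped unit-vector dot
products, reported in degrees (radians internally). Angles to
eigenvector axes use the acute convention (eigenvector sign is
arbitrary); species-vs-species angles do not, because direction is
meaningful. The "average direction" of a trajectory is the unit-normalized
vector sum of its growth vectors (equivalently the net-displacement
direction); a mean-of-unit-directions alternative is exposed.

Uncertainty comes from the matrix-normal sampling distribution of
contrast estimates, v* ~ N(v̂, Se ⊗ ΔL(X′X)⁻¹ΔL′), sampled without
materializing the Kronecker product by factoring each side through its
eigendecomposition (eigenvalues within −1e-10·scale of zero are clipped;
anything more negative is an error). Magnitude SEs are standard
deviations of draw norms; angle SEs are circular standard deviations
sqrt(−2 ln R̄) of draw angles. Angles between two vectors draw both
jointly (stacked contrasts) so the correlation induced by shared
coefficients — consecutive intervals share a stage mean — is kept.
1000 draws by default; point estimates are the default reported values,
with circular means of the draws alongside.

Raw norms of estimated vectors are biased upward (E‖v̂‖² = ‖v‖² +
tr(Se)·ΔL(X′X)⁻¹ΔL′) and raw angles are biased towards 90°, noticeably
so for short late-ontogeny steps. The package therefore also reports
bias-corrected magnitudes, rates, path distances and angles obtained by
subtracting the sampling-covariance trace from the estimated Gram matrix
(clipped at zero). Parameter-recovery tests use the corrected
estimators.

The random-direction null for an observed angle simulates pairs of
uniform directions in d dimensions, with d defaulting to the effective
tangent rank min(n − cells, 3k − 7); the dimension the null should use
is not identifiable from the data and is exposed as a parameter.

## Synthetic ontogenies and what the tests show

The generator's default spec is the study design the package targets:
3 species x 5 stages (7, 14, 35, 63, 100 days) x 6 specimens per cell
(≈ 90 mandibles), per-interval step magnitudes chosen so per-day rates
are front-loaded in the mouse-like species (0.021 then 0.002 per day
against 0.009/0.005 and 0.011/0.006) and path distances land near
0.26–0.28 Procrustes units, between-species angles of 37°/82.3°/76.39°
at the first interval narrowing to 39.28°/46.2° during weaning, and
weaning-deflection angles of 80.5°/70.5° before against 39.5°/58.4°
after. Angles that the emulated design leaves unspecified (gerbil–mouse
from 14 days on, all pairs after 63 days, the last within-species turn)
are set once to plausible values between 45° and 70°, consistent with
differences accumulating late in ontogeny. Landmark noise defaults to
sd 0.003 in shape units (≈ 0.3% of centroid size, a typical digitization
error scale); individual log-size jitter sd 0.05 around a schedule that
roughly doubles centroid size over the ontogeny; nuisance is a uniform
random rotation and a ±1-unit translation per specimen. The explicit
allometric shape component defaults to zero because the planted growth
vectors already represent the *total* stage-to-stage change, allometric
part included; a nonzero slope plants individual-level allometry for
testing the regression score.

Exactness is engineered, not approximate: planted effects are
displacement fields a ⊗ e (every landmark moves along one fixed spatial
direction by a per-landmark scalar) with the scalar field orthogonal to
the translation, rotation and scale couplings at the base shape, and
stage means are placed on the unit-centroid-size sphere. Under this
construction the identity rotation is exactly optimal at every
Procrustes step, so the pipeline output has a closed form the generator
computes as ground truth; requested magnitudes are realized exactly via
a fixed-point calibration of the planted step lengths, and requested
angles to within fractions of a degree (the tangent projection bends
them slightly; the realized values are what the ground truth records).
Angle structure across species and intervals is built sequentially from
3x3 Gram factorizations, so infeasible angle triples are detected and
named. The cost of this construction is that synthetic shape change is
geometrically special (single spatial direction, exactly
nuisance-orthogonal); passing tests therefore establish the statistical
machinery — estimation, transport, uncertainty, inference — not the
behaviour of GPA on large, fully 3D shape differences, where tangent
approximation and consensus estimation interact in ways the generator
deliberately avoids. Within-cell variation is i.i.d. Gaussian landmark
noise; real within-cell variation is anisotropic and structured, so
sampled SEs on real data will differ from the isotropic-noise SEs seen
in tests.

Problem sizes used by the test suite and the acceptance script — 40
landmarks, 90 specimens, 100 recovery replicates, 200 null simulations
for type-I calibration, 1000 permutations and draws — were chosen as the
smallest sizes at which the statistical checks are stable.

## Known limitations

- Exact Riemannian parallel transport is out of scope; the linear shift
  is an explicit Euclidean approximation.
- Sliding against a consensus recomputed each iteration is the Gunz
  convention; template mode exists but atlas construction (patch
  transfer from a template mesh) does not.
- Mesh handling is limited to nearest-point back-projection and TPS
  warping of vertices; rendering and colour mapping are out of scope.
- Mixed models, family structure and phylogenetic corrections are not
  implemented; family ids are carried as metadata only.
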