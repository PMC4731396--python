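# Methods

This note records the models, estimators and numerical choices behind
each stage of the pipeline, the design decisions taken where the
methodology is genuinely open, and what the synthetic-data generator
does and does not emulate.

## Superimposition

**Centroid size** is `sqrt(Σ_i |x_i − x̄|²)`; shapes are compared after
removing translation (centering), scale (unit centroid size) and
rotation (proper rotations only — all specimens are photographed in a
common orientation, so a reflection could only be an artifact).

**Fixed-angle correction.** The lateral view contains an articulated
mandible whose gape angle is preservation noise, not shape. Before
superimposition the jaw landmark subset is rotated rigidly about the
articulation pivot so the angle between the cranial ray
(reference → pivot) and the jaw ray (pivot → jaw-ray landmark) equals a
standard value, 40° by default, on the observed side of the cranial
ray. Within-jaw geometry is preserved exactly. The landmarks defining
the pivot and the two rays are user configuration
(`ArticulationSpec`); no convention fixes them anatomically.

**GPA with sliding semilandmarks.** The iteration is
{align every configuration to the consensus by translation/scale/proper
rotation; slide semilandmarks; recompute and re-normalize the
consensus} until the consensus moves less than `tol` (default 1e-8;
`max_iter` 10). Sliding minimizes the bending energy of each
specimen's deformation from the consensus — the quadratic form of the
bending-energy matrix of the consensus (upper-left block of the inverse
TPS system matrix, kernel `U(r) = r² log r²`) — over displacements of
each semilandmark along its local tangent, estimated by the central
difference of its curve neighbors in that specimen.

Two schedule details are ours:

* *Gauge constraint.* All specimens sliding along the outline together
  changes nothing relative, so the slide amplitudes have a flat
  direction that makes the naive iteration drift indefinitely. The
  slide step therefore minimizes the **total** bending energy jointly
  over specimens subject to a zero-mean slide per semilandmark
  (a Lagrange-multiplier solve). Because zero slide is feasible, total
  bending energy never increases — the monotonicity the tests assert.
* *Slide freezing.* Sliding is applied during the first
  `n_slide_iter = 5` iterations only; the sliding/consensus coupling
  contracts only geometrically (≈8% per iteration on smooth outlines),
  whereas plain GPA then converges in a few iterations. The residual
  energy left on the table is ~0.2% on typical data.

The final consensus is rotated to a canonical orientation (major
principal axis along +x, sign fixed by the third moment), which makes
GPA output deterministic and invariant to similarity transforms of the
input — an invariance the acceptance suite checks to 1e-8.

**Tangent projection** is the orthogonal projection
`y ↦ m + (y − m)(I − m mᵀ)` at the unit mean-shape vector `m`:
idempotent, fixes the mean, and preserves small-variation distances to
first order. Procrustes distance downstream is the Euclidean norm of
tangent-vector differences.

## Integration and combination

Two-block PLS takes the SVD of the between-block cross-covariance of
the column-centered view matrices; `r_PLS` is the Pearson correlation
of the first left/right scores, and significance comes from global
permutation of one block's rows (the observed case counting as one of
`n_perm`, so min P = `1/n_perm`). Within-group permutation is not
implemented; the test is of overall association.

The separate-subsets combination scales each view's unit-centroid-size
vector by `sqrt(CS_view / (CS_D + CS_L))`, dorsal block first. The
squared weights are the centroid-size shares, and the combined
configuration has unit centroid size identically — the contract the
pipeline asserts at 1e-12. The pipeline combines the *aligned* rows
(exactly unit norm) and tangent-projects the combined matrix once at
the combined mean. The integration test gates the combination only in
the advisory sense: a non-significant PLS raises a warning and the run
proceeds, flagging the caveat in the log.

## Shape models and RRPP

Head size is the log centroid size of the **dorsal** configuration.
Designs are built sequentially (Type I): intercept, then each term in
the stated order, factors treatment-coded with the first
(alphabetical) level dropped; a term that adds no rank raises an
error naming it. For term *i*, `SS_i` is the drop in summed squared
residuals from the model of preceding terms to the model through term
*i*; `F = (SS/df) / MS_res` of the full model; `R² = SS/SS_total`.

RRPP builds each term's null by permuting the reduced model's
residuals, re-adding its fitted values and recomputing `SS_i`;
`P` is the proportion of the `n_perm` values (observed included) at
least as large as the observed, with ties resolved by a 1e-12 absolute
tolerance. `Z` is the standard deviate of the observed SS in that
distribution, on the raw SS scale by default (`z_log_ss` switches to
log scale). Type-I-error calibration on pure-noise data is checked by
the acceptance suite (rejection rate in [0.03, 0.07] at α = 0.05 over
1,000 datasets).

**Model screening** fits the full candidate sequence (log_cs, each
factor, each factor×size interaction), retains terms with `P < α`
(α = 0.05) and keeps main effects of retained interactions; the report
ranks terms by Z. This screening rule is this package's own criterion
for the structure-selection step, and reports label it as such. On
data generated with a common slope and group offsets it returns the
common-allometry model `log_cs + group`. On the end-to-end synthetic
study a small `log_cs:group` term is occasionally retained even though
the generator uses one slope: GPA normalization and sliding are
nonlinear and induce tiny group-specific apparent slopes — genuine
signal of the processed data, not miscalibration.

**Pairwise tests.** A group's LS mean is its model prediction with
log_cs at the grand mean; with additional factors in the model the
covariate frame is counterfactually set to the group and averaged
(population-averaged LS means). The null distribution of each pairwise
distance comes from RRPP permutation of the group-free reduced model.
**Allometry-free shapes** are pooled-regression residuals plus the
prediction at grand-mean log_cs, so they live in shape space and are
exactly uncorrelated with size.

## Classification

Densities are correct multivariate normal log-densities with the
pooled within-group covariance. Because the covariance is pooled, any
density normalization constant cancels in the posterior, so the choice
of constant is immaterial to the results. Procrustes tangent data are
rank-deficient, so the data are first projected onto principal
components of the pooled within-group scatter, keeping at most
`min(q, n − k)` components with relative eigenvalue above 1e-10;
posteriors are computed by log-sum-exp.

Phylogenetic priors use the **Brownian covariance** `c_jk` (shared
root-to-MRCA path length), not raw patristic distance: patristic
distance is largest for the most distant pair, which would invert the
intent of priors based on relatedness. Priors are per-specimen,
conditioned on the specimen's current designation *j*, and normalized
over the hypothetical groups *k* for that fixed *j*. On a star tree
all off-diagonal covariances vanish and the prior degenerates to an
indicator on the designation; this is flagged with a warning. A zero
prior yields an exactly zero posterior.

Quartiles use linear interpolation (the "type 7" rule), so hand checks
on small sets match. A group is *distinct* when the IQR of its
members' correct-assignment posteriors overlaps the IQR of no
alternative assignment; an overlap is *reciprocal* when it appears in
both directions of a pair. Groups with fewer than four members are
marked not evaluable.

## Phylogenetic comparative machinery

Trees are rooted with positive branch lengths; pruning removes tips
and suppresses degree-2 nodes, summing lengths, so kept tips retain
their depths. Internal nodes are numbered `k+1, k+2, …` in preorder
after the `k` tips — with nine groups the ancestors are nodes 10–17.

**Squared-change parsimony** minimizes `Σ_edges |Δstate|²/length`
over internal states — a sparse linear solve per coordinate, exact,
and identical to the GLS reconstruction under Brownian motion (the
acceptance suite confirms both against a numeric optimizer and the
closed-form GLS oracle). Zero-length edges are floored at 1e-12 with a
warning. **Brownian simulation** draws tips from
`MVN(root, C ⊗ R)` with `C` the shared-path matrix; matrix square
roots use eigendecomposition with negative eigenvalues clipped at 0
(PSD enforced to −1e-8 relative).

**DTT.** Disparity of a tip set is the mean squared pairwise Euclidean
distance (singletons contribute 0). Relative node times are internal
node depths rescaled by the depth of the most recent divergence; the
curve starts at 1 at the root (single clade) and at each later node
time averages, over the lineages crossing that time, the subclade
disparity divided by whole-tree disparity. The analysis operates on
group-mean allometry-free shapes, not individuals. The envelope is the
pointwise median and 2.5/97.5 percentiles of `n_sim` Brownian
simulations with the rate matrix estimated from the tip data by
GLS/independent contrasts (`R = (X − 1â)ᵀ C⁻¹ (X − 1â)/(k − 1)`).

**MDI** defaults to the mean squared difference between the observed
curve and the simulation median (always ≥ 0; near 0 only when the
curves coincide); the signed area convention (mean of observed minus
median, which averages to ~0 under Brownian data) is also computed as
`mdi_area`, and outputs name which is which.

## Synthetic studies

The generator emulates a two-view museum study: group mean shapes are
the view templates (an elliptical head outline with sliding
semilandmarks plus fixed anatomical points; the lateral template adds
a rigid 12-landmark mandible hanging at 40°) perturbed by Brownian
deviations on the group tree; specimens add a common allometric
displacement for their lognormal head size, a latent integration
factor displacing both views, a rigid mandible rotation to a drawn
articulation angle, and iid Gaussian landmark noise; coordinates are
then scaled to image units. The default tree is a unit-height
ultrametric nine-group topology with an old 2-vs-7 basal split and
three recent sister pairs.

Default magnitudes (template units, unit-scale template):
`shape_rate = 0.0025` per coordinate per unit height,
`allometry_slope = 0.05` per log-size unit, `noise_sd = 0.005`,
`integration_sd = 0.01` with `view_integration = 0.5` (the fraction of
group-level Brownian variance shared between views — both views
project one head), log-size sd 0.25, articulation 45° ± 8°. They were
chosen so the synthetic study reproduces the magnitudes typical of the
real system: pairwise group shape distances ≈ 0.005–0.03, size and
group R² of a few percent each, classification accuracy near 1 at the
default 30 specimens per group, and a dorsal–lateral integration that
is usually (not always) significant at that sample size — at 10 per
group the PLS gate is under-powered and warns, which is the expected
behavior on small runs.

What the generator does **not** emulate: non-isotropic or landmark-
specific digitizing error, missing landmarks, within-group sexual or
ontogenetic shape dimorphism beyond allometry (sex and stage labels
are generated with zero effect, so model screening should drop them),
3D-to-2D projection distortion, and museum-preservation deformation
beyond the articulation angle. Passing tests therefore demonstrate
correctness of the estimators and calibration of the tests under the
stated model, not robustness to those real-data pathologies.

## Problem sizes and determinism

The default resampling conventions are 10,000 permutations/simulations
with α = 0.05; the `--fast` profile (999 permutations, 200
simulations) is used in the examples, and the test suite and
acceptance script run at desk scale (≤ 30 specimens per group, 999
permutations, ≤ 500 simulations) — sizes at which every calibration
property checked is already stable. Every random stage of the pipeline
consumes its own spawned child of the master seed, recorded in the run
log along with package and numpy versions; reruns with the same seed
are byte-identical, and the run log deliberately contains no
timestamps.

## Known limitations

* Sliding uses bending energy only (no perpendicular-projection
  variant) and 2D landmarks only.
* The PLS permutation is global; stratified (within-group) permutation
  is not offered.
* LS means marginalize extra factors by population averaging; other
  marginalization rules would need to be added for unbalanced designs
  with interactions beyond size×group.
* The classifier's PC truncation discards directions with no
  within-group variance, which would be infinitely discriminative in
  exact arithmetic; with realistic noise none exist.
* MDI magnitudes depend on the disparity statistic (mean squared
  pairwise distance) and on the node-time grid (all internal nodes);
  comparisons across software should check both conventions.
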