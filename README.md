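# vipermorph

Geometric-morphometric and phylogenetic-comparative species delimitation
for 2D landmark data.

Museum series of closely related forms — the motivating system is the
nine named subspecies of the Western Rattlesnake (*Crotalus viridis*)
complex — carry head-shape signal that can corroborate or contradict
molecular species hypotheses. This package implements the full analysis
chain a morphometrician needs to extract and test that signal:

1. **Landmark I/O** — tpsDIG-dialect TPS files for two views (dorsal,
   default 33 landmarks; lateral, default 50), a metadata CSV
   (`id,group,sex,stage`), a JSON curve specification naming the
   sliding semilandmarks, and a rooted Newick tree over the group
   labels.
2. **Superimposition** — the *fixed-angle* correction rotating the
   mandible rigidly about its joint to a standard 40° articulation,
   then generalized Procrustes analysis (proper rotations only) with
   *minimum-bending-energy sliding* of semilandmarks along their curve
   tangents, and orthogonal projection into the tangent space at the
   mean shape. Thin-plate-spline deformation grids visualize shape
   differences.
3. **Integration and combination** — a two-block partial least squares
   test of dorsal–lateral integration (r_PLS with a permutation P),
   then the *separate-subsets* combination
   `y_T = [ sqrt(CS_D/(CS_D+CS_L))·y_D , sqrt(CS_L/(CS_D+CS_L))·y_L ]`,
   which weights each view by its share of centroid size and yields a
   combined configuration of unit centroid size.
4. **Shape statistics** — linear models of shape on log centroid size
   and categorical factors, tested by non-parametric MANOVA with Type I
   (sequential) SS and the *randomized residual permutation procedure*
   (RRPP): per-term SS, MS, R², F, an effect size Z (the standard
   deviate of the observed SS in its permutation distribution) and a
   permutation P whose smallest attainable value is `1/n_perm`.
   Pairwise group differences are distances between least-squares mean
   shapes, tested against the RRPP null of the group-free model;
   allometry-free shapes come from the pooled regression on size.
5. **Bayesian classification** — each specimen is scored against every
   group's multivariate normal density (group centroid, pooled
   within-group covariance, computed in log space after projection onto
   the principal components of the within-group scatter), with either
   equal priors or *phylogenetically informed* priors
   `Pr(k) = c_jk / Σ_k c_jk`, where `c_jk` is the Brownian covariance
   (shared root-to-MRCA path length) between the specimen's designated
   group *j* and candidate *k*. Group distinctness is read off
   interquartile-range overlap of the posteriors.
6. **Phylogenetic comparative analysis** — weighted squared-change
   parsimony for ancestral shapes (the exact linear-system solution,
   which equals the GLS/Brownian reconstruction), multivariate Brownian
   simulation with tip covariance `C ⊗ R`, and disparity-through-time
   (DTT) curves with a simulated 95% Brownian envelope and the
   morphological disparity index (MDI).
7. **Synthetic studies** — a generator producing complete studies (TPS
   + CSV + Newick + ground-truth JSON) with group means evolved by
   Brownian motion on a nine-group tree, a common size allometry, a
   latent dorsal–lateral integration factor, a randomized mandible
   articulation, and isotropic landmark noise — every downstream stage
   is scoreable against known truth.

## Worked example

`examples/` contains one short script per capability. The full chain
(`python examples/06_full_pipeline.py`) simulates a nine-group study
(10 specimens per group), runs every stage with the fast resampling
profile and prints:

```
stages run: gpa, pls, manova, pairwise, classify, ancestors, dtt
r_PLS = 0.4392 (P = 0.2963)
           df      SS      MS      R2       F       Z      P
log_cs      1  0.0010  0.0010  0.0507  5.2226  7.2580  0.001
group       8  0.0034  0.0004  0.1721  2.2148  6.2654  0.001
Residuals  80  0.0152  0.0002     NaN     NaN     NaN    NaN
Total      89  0.0195     NaN     NaN     NaN     NaN    NaN
classification accuracy (phylo priors): 1.000
MDI = 0.0029
```

Reading it: head size and group are both significant shape predictors
(P = 0.001 is the smallest attainable value with 999 permutations;
Z is the effect size in permutation standard deviations); size explains
5% and group 17% of shape variance in this draw. Every specimen
classifies back to its generating group under phylogenetic priors. The
integration test is under-powered at 90 specimens (the gate warns and
proceeds); at the default 30 per group it is typically significant with
r_PLS ≈ 0.35–0.5. The MDI near zero says the group means disperse
about as a Brownian walk on the tree would — the generator's null —
whereas injected sister-pair displacement pushes late-time disparity
above the envelope (see `tests/test_acceptance.py`).

The same run from the shell:

```sh
vipermorph run-all --out out/ --simulate --n-per-group 10 --seed 6 --fast
```

writes `manova.csv`, `pairwise.csv` (distances below the diagonal,
P-values above), posterior and quartile tables for both prior schemes,
`ancestral_states.csv`/`ancestral_distances.csv`, `dtt.csv` and a JSON
run log with the per-stage seeds.

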