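# Methods

## Trait table and reduction

The raw table has 16 traits per species: six life-history durations (days),
adult body mass (g), diet and habitat breadths (counts, treated as
continuous), temperature mean/range (°C), precipitation mean/range (mm), and
three categorical variables — foraging stratum (ground/scansorial/arboreal),
activity cycle (nocturnal/diurnal/cathemeral) and trophic guild (folivore/
frugivore/folivore-frugivore/omnivore/gummivore/insectivore). An
`elevation_range_m` column is accepted in input files but excluded from the
analysis set: the 11-element schema is fully determined by the variables
above, and elevation range has no place in it. Species with any missing cell
are removed (no imputation).

The life-history block is z-scored (population scaling, 1/n) and collapsed
to its first principal component. PC1's sign is indeterminate, so the
component is oriented to give maximum longevity a positive loading: "slow"
life histories score high. This is a convention, not a claim; it makes runs
reproducible. A two-species table is allowed (the PCA is rank-1 and PC1
carries 100% of the variance).

## Factor analysis of mixed data

Quantitative columns are centred and scaled to unit (population) variance.
Each categorical level k with frequency p_k becomes an indicator column
divided by √p_k, then centred; levels never observed are dropped with a
warning, levels observed once are kept (their weight is large, which is the
honest consequence of the coding) with a warning. The covariance matrix
(1/n)ZᵀZ of the expanded matrix Z is eigendecomposed. Consequences used as
invariants: total inertia equals q + Σ(K_j − 1) (17 for the study schema);
coordinate variance per component equals its eigenvalue; with all components
retained, coordinate distances reproduce expanded-matrix distances.

Components are sign-fixed by making the largest-magnitude column loading
positive. The Kaiser criterion is strict (λ > 1, no tolerance band): a
component on the boundary is excluded. Per-variable contributions to a
dimension are squared unit-eigenvector loadings (×100), with category
contributions summed into their parent variable; the reporting filter
defaults to 9%.

## Uniqueness and specialisation

Uniqueness is the mean Euclidean distance to the k = 5 nearest neighbours
(self excluded) in the retained principal-coordinate space; specialisation
is the distance to the arithmetic centroid. Distance ties at the k-th
neighbour are resolved by species-id order so the neighbour set is exactly k
and deterministic. Robustness is reported as the Pearson correlation of the
uniqueness vector at k ∈ {1, 3, 10, 100} with the k = 5 vector. Outliers
use the Tukey upper fence (score > Q3 + 1.5·IQR), the standard boxplot
convention; only the upper tail is flagged since both scores are
non-negative isolation measures. Subset re-analysis (e.g. one radiation
only) reuses the full-space coordinates and restricts the neighbour
candidates and centroid to the subset; refitting the factor analysis on the
subset is available separately but is not the default, since the question
is positioning within the common space.

## Evolutionary models

All likelihoods are multivariate-normal with mean z0·1 and covariance
σ²·V(param), where V is built from the matrix S of shared root-to-MRCA path
lengths:

- Brownian motion: V = S (k = 2 parameters).
- Pagel's λ multiplies the off-diagonal of S, λ ∈ [0, 1].
- Ornstein–Uhlenbeck, single optimum, root fixed at z0 = θ, ultrametric
  height T: V_ij = exp(−2α(T − S_ij))(1 − e^{−2αS_ij})/(2α) (k = 3). This
  non-stationary three-parameter form keeps the model identifiable on
  ultrametric trees; the root convention is an explicit assumption.
- Early burst: time transform s′ = (e^{rs} − 1)/r with r < 0 (decelerating
  only; k = 3). Note the concave transform *raises* off-diagonal-to-diagonal
  ratios relative to BM — early shared history holds most of the variance.

For every structural parameter value, z0 and σ² are profiled in closed form
(GLS mean; mean squared Mahalanobis residual), so each fit is a 1-D search:
a pre-scan (21 equally spaced λ values; 50 log-spaced α ∈ [1e−8/T, 50/T] or
r ∈ [−10/T, −1e−8/T]) followed by bounded Brent refinement in the best grid
cell. The pre-scan guards against multimodality; the refined optimum is
accepted only if it improves on the grid. Solves use Cholesky
factorisations; a failed factorisation triggers one retry with 1e−10
diagonal jitter and a warning. A constant trait is an error, and a fitted
σ² of zero is returned flagged rather than silently.

λ is tested against both boundaries (λ = 0, no signal; λ = 1, BM) by
likelihood-ratio statistics referred to χ²(1); p-values are Holm-corrected
across dimensions within each tree, with the λ=0 and λ=1 families adjusted
separately. Models are compared by AICc = −2logL + 2k + 2k(k+1)/(n−k−1) and
Akaike weights; the smallest AICc wins. Because OU and EB nest BM as a
boundary, their ML log-likelihoods can never fall below BM's (checked to
1e−5); AICc's parameter penalty is what lets BM win.

## PGLS

The response is min–max scaled to [0, 1]; continuous predictors are centred
and scaled to unit variance (sample sd); categorical elements enter as
treatment dummies with reference levels folivore / arboreal / nocturnal,
giving 18 terms with the intercept. β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with σ̂² =
residual quadratic form/(n − p), two-sided t tests on n − p df. The error
covariance defaults to the BM structure of each tree — the minimal choice
consistent with the stated regression — with an ML-λ structure available
behind a flag for sensitivity analysis. Holm correction is applied within
each tree across all 18 terms (the intercept included, since its
significance count is reported like any other term); "significant" means
adjusted p < 0.05, and counts are taken across the tree sample. Reported
medians are rounded to 4 decimals.

## Synthetic data generator

The generator's defaults are the study conditions: 191 species, 100 trees.
Trees are one reference Yule topology (forward simulation, extinct lineages
pruned for the birth–death option) rescaled to unit height, plus 99 dating
variants obtained by the monotone node-age map d → d^γ, γ = exp(N(0, 0.3)).
This emulates the salient property of a node-dating posterior — shared
topology, varying divergence times. It does not emulate topological
uncertainty, so pipeline results cannot show robustness to topology errors.

The six life-history variables are √s·(latent BM score) + √(1−s)·noise on
day scales chosen to keep values positive; the expected PC1 share of the
block is (1 + 5s)/6, so the default target share 0.806 fixes s = 0.7672.
Mass is exponentiated BM around 3 kg; climatic variables are BM or OU with
moderate rates; breadths are discretised OU latents; categorical traits are
symmetric-Mk simulations with a slow rate (0.3 transitions per tree height)
for stratum and activity and a fast rate (8.0) for guild, making guild
effectively free of phylogenetic structure. If a draw leaves a declared
level unobserved the seed is bumped deterministically until all levels
appear, so the inertia identity holds on every generated dataset. A known
coefficient vector links the design matrix to an optional response for
regression recovery. Everything — config, derived child seeds, per-variable
models, β — is serialised in a truth record; a dataset is a pure function
of (config, seed).

What the generator does not attempt: real primate trait values or
correlations beyond the life-history block, geographic or climate-raster
structure, trait-dependent diversification. Passing tests demonstrate
correctness of the estimators under their own model classes and the
pipeline's determinism, not ecological realism.

## Problem sizes and numerics

Unit tests run at 10–80 species; recovery simulations use 100 replicates on
150–200-tip trees and 100-tree samples; the end-to-end determinism check
runs the full 191-species × 100-tree study twice. Oracle comparisons are at
1e−8 (eigenstructure), 1e−10 (GLS algebra) and 1e−5 (likelihood limit
equivalences); brute-force metric oracles agree to machine rounding (1e−14
relative, reflecting summation-order differences only). Degenerate inputs —
constant traits or columns, empty tables, subsets smaller than k,
non-ultrametric trees under OU/EB, rank-deficient designs — raise typed
errors naming the culprit rather than propagating NaNs. Near-zero negative
branch lengths (> −1e−9) are clamped to zero with a warning.

## Known limitations

- The OU fit assumes the root at the optimum; on non-ultrametric trees OU
  and EB are refused rather than approximated.
- λ, α and r are searched on [0,1], [1e−8/T, 50/T] and [−10/T, −1e−8/T];
  selection stronger than α = 50/T is reported at the bound.
- The platyrrhine-style subset re-run reuses full-space coordinates; a
  subset-refit FAMD answers a different question and is not wired into the
  pipeline.
- Uniqueness at large k approaches a central-tendency measure; the k = 100
  robustness entry is only meaningful when n ≫ 100.
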