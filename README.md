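# nichescape

Builds a multidimensional niche space for a species assemblage from mixed
trait data and asks how positions in that space evolved and which niche
elements predict interspecific competition. The pipeline was designed around
a primate-scale problem — ~191 species described by 16 raw traits and a
sample of 100 time-calibrated phylogenies — but every stage is generic.

## The analysis

1. **Trait reduction.** Six highly correlated life-history durations
   (gestation, weaning age, age at first reproduction, interbirth interval,
   generation length, maximum longevity; days) are collapsed to the first
   principal component of their z-scored block — the *life-history score* —
   leaving 11 niche elements: 8 continuous (life history, adult body mass,
   diet breadth, habitat breadth, temperature mean/range, precipitation
   mean/range) and 3 categorical (foraging stratum, activity cycle, trophic
   guild).
2. **Niche space.** Factor analysis of mixed data (FAMD): quantitative
   columns are z-scored, each categorical level k is coded as an indicator
   scaled by 1/√p_k and centred, and the expanded matrix is decomposed by
   PCA. Total inertia is q + Σ(K_j − 1) = 17 for this schema. Dimensions
   with eigenvalue λ > 1 (Kaiser criterion) define the niche space; species
   coordinates are principal coordinates (per-axis variance = eigenvalue).
3. **Competition metrics.** *Uniqueness* U_i = mean Euclidean distance from
   species i to its k = 5 nearest neighbours (low U ⇒ intense interspecific
   competition); *specialisation* S_i = distance to the centroid. Outliers
   are scores above the Tukey fence Q3 + 1.5·IQR.
4. **Evolutionary dynamics.** Per dimension and per tree: Pagel's λ by
   maximum likelihood with likelihood-ratio tests against λ = 0 and λ = 1
   (χ², 1 df, Holm-corrected across dimensions), and ML fits of Brownian
   motion (rate σ²), single-optimum Ornstein–Uhlenbeck (selection strength
   α) and early burst (rate decaying as σ²e^{rt}, r < 0), compared by AICc
   weight.
5. **Competition model.** PGLS of the min–max-scaled score on the 11
   elements, S = intercept + var₁ + … + varₙ, with a Brownian error
   covariance from each tree, within-tree Holm correction, and counting of
   significant terms across the tree sample.

Because the original compiled trait table and dated trees are third-party
downloads, the package ships a synthetic-data module that generates the
full study shape — trees (a reference Yule topology plus node-age variants
emulating a dating posterior), a 16-trait table with a tunable life-history
factor structure, Mk-simulated categorical traits — with every generating
parameter recorded, so all inference code is validated by parameter
recovery.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/02_build_niche_space.py
```

prints (seed 1):

```
simulated 191 species x 16 traits and 100 trees (seed 1) -> results/synthetic_study
life-history latent share 0.7672 targets a PC1 share of 80.6%
15 variable pairs with |r| > 0.6 (15 within the life-history block)
life-history PC1 explains 80.3% of the variance in the six duration variables
total inertia 17.0; 8 dimensions retained under the Kaiser criterion, explaining 67.5% of variance
  Dim1 (15.7%): activity_cycle 19%, life_history 19%, temperature_mean_c 17%, ...
```

i.e. the life-history PCA recovers the construction's 80.6% target, the
inertia identity (17) holds, and the Kaiser rule keeps 8 of 17 dimensions.
`analysis/03_niche_competition_metrics.py` then reports the uniqueness
robustness correlations (k = 1/3/10/100 vs k = 5: 0.79/0.97/0.97/0.75 on
this dataset) and outlier counts, `analysis/04_evolutionary_dynamics.py`
the per-dimension median λ and percentage of trees selecting each model
(Dim1: median λ = 0.99, BM selected on 92% of trees), and
`analysis/05_competition_pgls.py` the 18-term PGLS summaries with
significant-tree counts.

The same stages are scriptable via the CLI (`nichescape run|simulate|famd|
metrics|signal|pgls`) or the library API.

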