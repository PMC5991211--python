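# Methods

## The marginal model

The object being modelled is the vector of genome-wide single-variant
association statistics `χ²_1 … χ²_n` of a complex trait, ordered along the
genome. Only the first two moments are specified:

    E[χ²_l]   = β₁ + C_study · l_l · β₂
    Var(χ²_l) = φ · (E[χ²_l])²

`l_l` is the LD score of variant *l*: the sum of squared correlations r²
between *l* and every variant within 1 cM, including itself (so `l_l ≥ 1`).
Confounding (stratification, heterogeneity) inflates all statistics
uniformly and lands in `β₁ = 1 + Na`; polygenic signal inflates statistics
in proportion to how much LD they tag and lands in `β₂`, which equals the
heritability `h²` on the observed scale once the design constant absorbs
the per-SNP scaling `1/M`. The quadratic variance is exact for squared
normal scores (`φ = 2`), but `φ` is treated as a free nuisance parameter
and estimated, not assumed.

### Design constants

`C_study` converts per-SNP heritability into expected statistic inflation
and depends only on a-priori design knowledge:

| design        | C_study |
|---------------|---------|
| quantitative  | `N / M` |
| case-control  | `n_cases · n_controls · c² / ((1−K)² · N · M)` |
| family (FBAT) | `c² · (N/2) · ((1−z) n_a + z K/(1−K) n_u)² / ((1−z)² n_a + z² n_u) / M` |
| mixture       | weighted sum of component constants |

`K` is the disease prevalence and `c = t/K` the liability-scale factor,
with `t` the standard-normal density at the `1−K` quantile. The family
constant covers any per-family mix of `n_a` affected and `n_u` unaffected
offspring with FBAT offset `z`; at `z = 0` the unaffected count cancels
and the constant reduces to the trio form `c²N/(2M)`. The liability link
`q² = 2p(1−p)(λ−1)²/c²` connects a relative risk `λ` at MAF `p` to
explained liability variance; it is what makes `β₂` interpretable as
heritability under small multiplicative effects.

Mixture weights are not dictated by the model; the default weights
components proportionally to their sample sizes (the inverse-variance
choice when per-study statistics are equally scaled) and explicit weights
can be supplied instead. `M` is the number of common SNPs (MAF ≥ 5%) used
when the LD scores were computed; LD scores are always taken from the
reference panel, never re-estimated from the study.

No liability-scale transformation is applied to the estimated
heritability: the transformation is a known constant factor
(`c² n_cases n_controls / (N²(1−K)²)` for case-control designs), so the
observed-scale estimate plus that constant carries the same information.

## Estimation

### GEE instantiation

The genome is partitioned into consecutive 1 cM blocks per chromosome
(half-open intervals anchored at the map origin); the statistics in block
*i* form cluster `y_i` with covariates `X_i = [1, C_study · l]`. For the
gamma-type family implied by the two moments — identity mean link, variance
∝ mean² — the general GEE objects collapse to

    D_i = X_i,      V_i = diag(μ_i) R_i diag(μ_i),

with `R_i` the working correlation: the reference panel's r² submatrix for
the block. (For squared statistics, r² is the natural working correlation:
z-scores of adjacent variants correlate like the signed r, so their
squares correlate like r².) The dispersion `φ` scales the estimating
function and cancels at the root; it is dropped during solving and
reported afterwards via the Pearson moment estimator
`φ̂ = Σ((y−μ̂)/μ̂)² / (N−p)`.

The estimating equations `g_n(β) = Σ_i D_i' V_i⁻¹ (y_i − μ_i) = 0` are
solved by Fisher scoring. The full scoring step is the classical
iteratively-reweighted update, which converges at a linear rate without
being monotone in any residual norm, so the line search only guards
against real trouble: a step is halved when it would make any mean
nonpositive (identity link on a positive mean is not positivity-preserving
along the path) or when it increases the affine-invariant merit
`q = g' H⁻¹ g` more than tenfold, where `H = Σ D_i' V_i⁻¹ D_i`. `q` is
zero exactly at a root and puts the two score components — whose raw
scales differ by the LD-score magnitude — on a common footing. Convergence
is declared at `max|Δβ| < 1e−8` or `q < (1e−8 · n_clusters)²`; default
iteration cap 200, halving cap 30; non-convergence is flagged on the
returned fit, never silent. The default start `β = (mean(y), 0)` is always
admissible for nonnegative responses. Cholesky factors of the `R_i` are
computed once per problem and shared across iterations and replications.

### Sandwich variance with correlated clusters

Blocks are 1 cM long and LD is treated as zero beyond 1 cM, so only
*adjacent* blocks on the same chromosome share correlated statistics.
The covariance of `β̂` therefore uses the cross-cluster-corrected sandwich

    Σ̂ = H⁻¹ M̂ H⁻¹,
    M̂ = Σ_i g_i g_i' + Σ_{(i,j) adjacent} (g_i g_j' + g_j g_i'),

which reduces to the classical independence sandwich when the adjacency
set is empty. The per-coordinate Wald statistic `W_b = β̂_b² / Σ̂_bb` is
referred to χ²(1). Two small-sample facts are surfaced rather than hidden:
with very few clusters the corrected `M̂` can be indefinite (a negative
diagonal yields NaN standard errors, and serialized Wald entries become
null), and the χ²(1) calibration of the Wald test needs the cluster count
the asymptotics assume — of order several hundred (a genome supplies a few
thousand 1 cM blocks). A model-based covariance `φ̂ H⁻¹` is reported
alongside for diagnostics.

### Working matrices

Working correlations are the per-block principal submatrices of the band
r² matrix, repaired to positive definiteness by eigenvalue clipping
followed by renormalization to unit diagonal. The clip floor is `1e−3`:
besides guaranteeing a Cholesky factorization, the floor bounds the
condition number of each `R_i` (roughly `m/floor`). This matters because
the near-null eigendirections of an *estimated* r² block are panel noise,
and `V_i⁻¹` weights them by `1/floor`; with a floor of `1e−6` the
estimating equations put enormous weight on contrasts the data cannot
inform and the scoring iteration can diverge, while `1e−3` keeps the
perturbation of the matrix negligible and the iteration stable. Variants
in (near-)perfect LD (pairwise r² > 0.999) are collapsed to one
representative before matrices are formed — the same exclusion applied to
real input — which removes the worst degeneracies at the source.

Shrinkage towards the identity, used to emulate a mismatched reference
panel, follows the convex-combination convention `R' = s·R + (1−s)·I`
(off-diagonals multiplied by `s`), which preserves positive definiteness
for any `s ∈ [0, 1]`.

### The explicit WLS comparator

The efficiency benchmark is an explicit weighted linear regression of the
χ² statistics on `[1, C_study·l]` with weights

    w_l = 1 / ( l_l^(win) · 2·μ_l² ),

the product of an overcounting part (the reciprocal LD score of variant
*l* restricted to the regression SNP set) and a heteroscedasticity part
(the inverse variance of a statistic with mean `μ_l`, with the true
simulation parameters plugged in — the idealized weights). It is a
closed-form estimator; its standard errors come from empirical replication
spread, deliberately avoiding the block-jackknife machinery whose block
count materially influences results. Relative efficiency is reported as
`100 · Var(β̂, GEE) / Var(β̂, WLS)` per coordinate; below 100 means the
GEE estimator is more precise.

## The synthetic-data generator

The harness needs summary statistics with genome-like LD but without any
external download. Reference haplotypes are produced by coalescent
simulation (msprime): by default 200 haplotypes at effective population
size 10⁴, mutation rate 1.2e−8 per bp per generation, and a 1 cM/Mb map in
which 80% of the recombination is concentrated in ~2 kb hotspots spaced
~80 kb apart. The hotspot structure is essential, not cosmetic: a uniform
map makes LD scores nearly constant along the genome, which leaves the
intercept/slope decomposition of the model barely identified; hotspot maps
produce the wide LD-score spread seen in real panels. Only common variants
(MAF ≥ 5%) are kept.

Each study consists of independent regions (default 5 regions of 5 cM).
Within a region the regression set is an even thinning of the common
variants, after perfect-LD collapse; LD scores are computed for each
regression variant against the *full* common-variant panel within 1 cM —
exactly how pre-computed LD-score files relate to a pruned regression SNP
set, and the reason simulated LD scores reach realistic magnitudes (tens
to hundreds) rather than the row sums of the thinned set.

z-scores are drawn mean-zero multivariate normal with marginal variance
`β₁ + C·l_l·β₂` and correlation equal to the *signed* r among regression
variants (band-truncated at 1 cM, PSD-repaired, exact eigendecomposition
square root), so that the squared statistics have correlation r² — the
premise the working matrices encode. Generation LD is truncated at 1 cM
while clusters are 1 cM blocks, so cross-block correlation between
adjacent blocks exists by construction, exercising the corrected sandwich.
The matrices used for generation and the working matrices used for fitting
are distinct objects; the shrinkage scenarios (`s = 1` correct, `s = 0.64`
strongly misspecified) act only on the latter. An optional
`draws_per_region_set` stacks independent copies of the region set,
mimicking a genome larger than the simulated template.

What the generator does **not** emulate: ascertained case-control
sampling (statistics are drawn directly on the χ² scale, as the marginal
model describes them); signed effect directions or a realistic effect-size
distribution (only second moments matter to the estimators); allele
frequency–dependent architectures; LD differences between panel and study
population (misspecification is emulated parametrically via shrinkage);
and non-normal tails of real test statistics. Passing tests therefore
demonstrate correctness and efficiency of the estimation machinery under
the stated model, not robustness to every way real data violate it.

## Study geometries and problem sizes

Three replicated studies back the statistical tests and the acceptance
script; their sizes are chosen so each targets the regime its claim is
about while remaining desk-scale:

* **Recovery** — 5 regions × 500 regression SNPs (~25 clusters), truth
  `(1.02, 0.001)`, 200 replications: unbiasedness of both coordinates,
  judged against 3 Monte-Carlo standard errors of the mean.
* **Calibration / efficiency** — 20 regions × 125 SNPs (~100 clusters),
  500 replications, scenarios `s = 1` and `s = 0.64`: sandwich-SE
  calibration (mean estimated vs empirical SE) and relative efficiency.
  Sandwich accuracy is driven by the number of clusters, not the number of
  SNPs, hence the flatter geometry at the same 2,500 statistics.
* **Wald null calibration** — the same region set with 5 stacked draws
  (~500 clusters), `β₂ = 0`, 1,000 replications: empirical size of the 5%
  Wald test of the slope. The χ²(1) reference is asymptotic in the cluster
  count; several hundred clusters is the scaled-down analogue of the few
  thousand blocks a genome provides.

The dispersion check uses 10⁶ squared normal draws through the Pearson
estimator. All randomness flows from explicit integer seeds; identical
seeds give bit-identical results.

## Known limitations

* The family-design constant rests on a second-order Taylor approximation
  in the relative risk around 1; exact non-central-parameter formulas for
  specific family types are out of scope.
* Per-coordinate Wald tests only; no general contrast-matrix inference.
* The solver is written for general `p` covariates but everything shipped
  uses `p = 2`; growing-dimension asymptotics are not exercised.
* Working correlations derive from phased-haplotype r² (or dosage
  correlation); no LD estimation from unphased genotypes beyond that, and
  no imputation of the panel.
* With few clusters the corrected sandwich can be indefinite and the Wald
  test anti-conservative; both are reported, not corrected.
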