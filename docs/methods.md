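# Methods

## The model family

`coopsem` implements a two-sample, three-level structural equation model for
ordinal breeder-year data from a group-living bird population. Each breeder
(female or male) observed in a year contributes seven ordinal indicators
measuring three latent variables:

| Latent | Indicators (reference first) | Categories |
| --- | --- | --- |
| R — reproduction | within-group offspring, extra-group offspring, one-known-parent offspring | 4, 3, 3 |
| SE — social environment | group size, number of helpers | 5, 3 |
| TQ — territory quality | territory size class, insect availability class | 4, 4 |

Each ordinal indicator `y` is a thresholded version of an underlying
continuous variable `y' = λ·(latent) + ε`, `ε ~ N(0, 1)` (probit convention:
the measurement residual is fixed at 1, reference loadings are fixed at 1, so
latent scales are set by the reference indicators). Category `k` is observed
when `τ_{k-1} < y' ≤ τ_k` for a strictly increasing threshold vector `τ`.
There are no separate indicator intercepts: with ordinal data, intercepts and
thresholds are confounded, so intercept invariance between the sexes is
realised as invariance of the threshold vectors.

Every latent variable decomposes into three independent Gaussian shock
levels — between-group (territory), between-individual, and within-individual
(observation) — with level-specific variances. The female and male breeder of
a territory-year share the group-level shocks; an individual's years share its
individual-level shocks. Structural layer, per record:

* direct models: `R = β_SE·SE + β_TQ·TQ + γ1·z + γ2·z² + e_R`
* mediated models: `SE = b·TQ + e_SE`, `R = β_SE·SE + γ1·z + γ2·z² + e_R`

where `z = (age − 5) / 3` is standardised age and `e` the summed own-level
shocks. Loadings and structural paths act on the total latent values; the
level decomposition enters through the shock variances. The age coefficients
and the R-side measurement parameters are invariant between the sexes in all
ten models; the competing models differ only in which SE/TQ blocks (effect on
R — or TQ→SE in the mediated family — indicator thresholds, indicator
loadings) are constrained equal between the sexes. `M1`–`M6` are direct with
progressively more constraints (M6 fully invariant); `M7`–`M10` are mediated.
The constraint grid is encoded in `coopsem.specs` and rendered by
`render_constraint_table()`.

One documented ambiguity is surfaced rather than resolved: the reported
constraint-grid table and the accompanying prose disagree about which effect is
invariant in the mediated models M8/M9. The grids in this package follow the
table (M8: SE effect invariant, TQ→SE free; M9: the reverse).

The senescence onset is the vertex of the quadratic age effect,
`−γ1/(2γ2)`, mapped back to years.

## Inference

`coopsem.gibbs` implements Metropolis-within-Gibbs with ordinal data
augmentation; no external MCMC engine is used. Per sweep:

1. **Thresholds** — joint random walk on (first cut point, log spacings),
   accepted against the ordinal likelihood with `y'` integrated out (the
   augmented values are redrawn immediately afterwards, making this a valid
   partially collapsed update). Step sizes adapt toward 35% acceptance during
   burn-in only.
2. **Augmentation** — truncated-normal draws of `y'` cell by cell; cells with
   missing indicator values get unconstrained normal draws, which is exactly
   missing-at-random imputation inside the chain.
3. **Latent shocks** — conjugate multivariate-normal block updates at the
   observation, individual and group level (3×3 solves, batched).
4. **Loadings, structural paths, age coefficients, mediation path** —
   conjugate normal updates, pooling the two samples wherever a ♀=♂
   constraint applies, so constrained parameters are draw-wise identical
   between the sexes by construction.
5. **Variance components** — conjugate inverse-gamma, or under the
   half-Cauchy prior an independence Metropolis proposal from the flat-prior
   conditional `IG((n−1)/2, ss/2)`, whose acceptance ratio reduces to
   `(A²+σ²)/(A²+σ²′)`. This was verified against numerical integration of
   the exact conditional.
6. **Latent-scale moves** — a joint Metropolis rescaling of one latent's
   shocks, variance components, free loadings and attached paths. The move
   leaves every indicator mean except the latent's reference column exactly
   unchanged, so it travels along the soft ridge between a latent's scale and
   its coefficients that single-site Gibbs crosses extremely slowly. A
   20% mixture component proposes large jumps (log-scale s.d. 1.5) so chains
   can cross between well-separated scale regimes.

The sampler's correctness is established by a joint-distribution
(simulator-vs-sampler) test (`coopsem.validation`): alternating exact forward
draws of data given parameters with Gibbs transitions of parameters given data
leaves the prior as the stationary parameter marginal; Kolmogorov–Smirnov
tests against the analytic prior CDFs must pass. This test caught two real
bugs during development (a missing Jacobian cancellation in the scale move;
threshold-update autocorrelation masquerading as bias), which is why it is
kept as a first-class acceptance test.

### Priors

Defaults: `Normal(0, 2.5²)` on free loadings, structural paths and age
coefficients; ordered `Normal(0, 2.5²)` on thresholds; `half-Cauchy(0, 1)` on
level standard deviations (inverse-gamma selectable). All observed variables
are ordinal with unit probit residuals, so every parameter lives on a
standardised scale where magnitudes beyond ~2.5 are implausible; the priors
encode that and nothing more. Genuinely vague settings (`coef_sd=10`,
`hc_scale=2.5`) are available through `Priors`, but on desk-scale ordinal
data they place most prior mass in scientifically impossible regions and
leave two pathologies that we observed directly: a degenerate regime in which
one latent's group variance inflates by an order of magnitude while its
non-reference loading collapses to zero, and a variance-collapse trap in
which all of a latent's levels are driven to zero and the unit-residual
anchor makes single-move escape essentially impossible. Weakly informative
priors remove the posterior mass that feeds both.

Initialisation: free loadings start at 1 (the reference scale) plus jitter,
thresholds at normal quantiles of the empirical category frequencies,
variances at 1, everything else at 0; chains are overdispersed by
seed-controlled jitter so the Gelman–Rubin statistic is meaningful.

### Diagnostics

`gelman_rubin` implements the between/within form
`sqrt((W + B/n) / W)` so duplicate chains give exactly 1.0; the operative
convergence standard is 1.05. `hpdi` returns the shortest contiguous interval
containing the requested mass. Posterior summaries include the senescence
onset in years, computed per draw where `γ2 < 0`.

## Model comparison

The criterion combines posterior-predictive variance and ν-weighted squared
discrepancy over all observed cells of the underlying continuous data; lower
is better, ν defaults 0.5 and 0.8, and models within 2 of the best are
resolved by parsimony (fewest free parameters). For ordinal cells the
"observed" continuous value is the posterior mean of the augmented `y'` —
the usual convention for threshold models. A `literal_discrepancy` switch
exposes the degenerate reading in which the replicate appears in both terms
(its expectation is then just the variance component again); it exists for
sensitivity analysis only. Missing cells are excluded from both sums.

Replicate moments are Rao-Blackwellised: since `y_rep = mean + ε` with unit
ε, `Var(y_rep)` is computed as the variance of the cell means over draws plus
one, and `E(y_rep)` as the mean of the cell means, removing all synthetic
replicate noise from the criterion. This cut the criterion's chain-to-chain
standard error several-fold in our experiments.

A genuine limitation, documented deliberately: among the nested
sex-invariance variants (M1–M6) the criterion differences are intrinsically
small — for the 21-year field dataset of this system the full spread across
M1–M6 is a few tens on a criterion total of ~22 000 — and shrink proportionally with dataset size. At the
reduced sizes used in the test-suite the expected difference between the
fully invariant model and its one-parameter relaxation is of the same order
as the dataset-to-dataset sampling variability, so the selection experiments
use the minimal model pair bearing on the sex-difference question (M5 vs M6)
and a majority-of-replicates standard rather than per-replicate certainty.

## The synthetic-data generator

`coopsem.simulate` draws from exactly the generative process the model
assumes: group/individual/observation shocks, the structural equations of the
chosen model, `loading × latent + unit noise`, thresholding. Defaults mirror
the study population: 110 territories, five seasons, one breeding female and
one breeding male per territory-year sharing the territory shocks, breeders
holding territories for at least two consecutive years, ages 1–13. Default
generating values follow the qualitative pattern of the published estimates —
a clear positive SE→R effect (0.6), a near-zero TQ→R effect (0.1), positive
linear and negative quadratic age coefficients placing the senescence onset
at seven years — with magnitudes chosen to be realistic rather than copied, since field
estimates for this system are reported graphically. Missingness is applied only to
the four group-level indicators reported to contain missing data, masking
cells independently (missing completely at random, a special case of the
missing-at-random assumption the imputation requires).

What the generator does **not** emulate: non-random missingness, temporal
trends in territory quality, spatial autocorrelation between territories,
helper co-breeding, divorce/re-pairing dynamics within a season, and
selection of which variables were discretised into how many categories (the
true category counts are unpublished; the defaults 4/3/3/5/3/4/4 are
configurable). Passing recovery tests therefore demonstrate correctness of
the inference under the model's own assumptions, not robustness to their
violation.

## Problem sizes in the test-suite

Recovery uses 20 replicates of 100 territories × 5 years with single chains
of 2 200 iterations; selection uses 5 replicates per scenario of 60
territories × 5 years; the joint-distribution test uses 20 records and
30 000 cycles per seed; the full default configuration (3 chains × 10 000)
is reserved for real analyses. These sizes keep the whole suite to roughly
twenty minutes on one core while leaving each experiment enough resolution
for its pass criterion.
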