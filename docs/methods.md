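# Methods

## The estimand and the study design

The quantity of interest is, per species, the difference between its
occupancy trend inside protected areas and the trend it would have had
without protection. Because protection is assigned non-randomly, the
package approximates the counterfactual with a matched design: each
protected site is paired with the most similar unprotected site (same
vegetation zone, similar land cover, survey history and effort), and the
trend model is fitted to matched sites only. The protection × year
interaction β_int then measures the trend difference attributable to
protection, on the probit scale per year.

## Protection assignment

A site is protected when a taxon-specific buffer around its survey
geometry overlaps any PA polygon with positive area: 500 m around bird
transect lines; for mammal wildlife triangles a disc centred at the
triangle centroid reaching 500 m beyond its vertices (a literal reading
of "extending 500 m beyond its vertices" that avoids polygon dilation);
100 m discs for plants (sessile organisms, coarser coordinates); the
lake polygon itself for phytoplankton. All geometry is planar with metre
units; at study scale (hundreds of km) the geodesic error is negligible.
When several PAs intersect a buffer, moderator attributes (size ha, IUCN
category, establishment year) come from the PA with the largest overlap
— the attribution rule is a package decision; no convention is
established in the literature. An optional minimum-coverage threshold
(default 0: any positive overlap) supports coverage sensitivity
analyses.

## Matching

Propensity scores are fitted probabilities from a logistic model of
protection on the matching covariates (8 land-cover proportions, mean
survey year; plus survey effort for birds/mammals and 4 lake covariates
for phytoplankton), estimated by Newton/IRLS to a relative log-likelihood
tolerance of 1e-8 (max 100 iterations). Perfect or quasi-separation
(detected as non-convergence or |logit| > 15 on standardized covariates)
triggers a ridge-stabilized refit with a warning. Zero-variance
covariates are dropped — they carry no information and would make the
Hessian singular.

Matching is one-to-one greedy nearest-neighbour without replacement,
inside exact vegetation-zone strata. Treated units are processed in
descending propensity score with site-id tie-breaks — the processing
order is unstated in the matching literature's defaults, so it is fixed
here for determinism. Each treated unit receives the closest unused
control whose propensity-score distance is within 0.25 × SD(scores), or
is dropped. With the Mahalanobis metric the nearest control is chosen by
Mahalanobis distance on the covariates (pooled within-group covariance,
ridge 1e-8), while the caliper still constrains the score distance, the
scale on which calipers are conventionally defined. Balance is the
absolute standardized mean difference |mean_t − mean_c| /
sqrt((s²_t + s²_c)/2) per covariate, before (all treated vs all
controls) and after matching; of the two candidate designs the one with
the smaller mean absolute after-SMD wins, ties broken toward more pairs,
then toward the propensity method. Optimal (non-greedy) matching and
matching with replacement are deliberately out of scope.

## The trend model

For sampling unit u (a surveyed site-year) and species j:

    z_uj = x_u' β_j + a_site(u) + b_year(u) + ε_uj,  ε ~ N(0, 1)
    y_uj = 1[z_uj > 0]

Fixed-effect columns: intercept; protected (0/1); year t rescaled so the
earliest survey year is 1; protected × t; two zone indicators (HSB
baseline); standardized log effort (birds/mammals) or log lake size
(phytoplankton). Continuous covariates other than the year index are
standardized and the transform recorded — whether to centre effort is a
genuinely open choice; standardizing stabilizes the sampler without
changing the interaction estimand. Species coefficients are pooled
through β_j ~ N(μ, V); site and year random intercepts are exchangeable,
shared across species, with inverse-gamma variances. The temporal random
effect is omitted for plants (too few survey years to identify it).

This replaces the spatially structured latent-factor residuals of full
joint species distribution frameworks with exchangeable random
intercepts plus community pooling — a deliberate simplification that
preserves the inferential target (β_int) and the hierarchical sharing of
information across rare species while remaining exactly conjugate and
testable at desk scale. Spatial covariance kernels and phylogenetically
structured priors on B are out of scope.

### Sampler

Gibbs with latent-utility data augmentation:

1. z_uj ~ N(x_u'β_j + REs, 1) truncated to the orthant given y_uj,
   drawn by inverse-CDF with probabilities clipped to [1e-15, 1−1e-15]
   and a sign safeguard deep in the tails;
2. each β_j from its multivariate-normal full conditional — the
   posterior precision XᵀX + V⁻¹ is shared across species, so one
   Cholesky factorization updates the whole coefficient matrix;
3. (μ, V) from a Normal-Inverse-Wishart update with κ0 = 0.04,
   ν0 = p + 2, S0 = I. A fully independent μ ~ N(0, 25 I) prior would
   not be conjugate jointly with V; the NIW form with small κ0 keeps the
   mean similarly diffuse (Var(μ) ≈ 25·V̄) while every update stays
   exact;
4. site/year random intercepts from conjugate normal conditionals,
   variances from InverseGamma(1, 1) updates.

Chains differ by seed and overdispersed initialization (coefficient
init SD grows with chain index). No recentring or reparameterization
moves are applied: the additive flat direction between the species
intercepts and the site intercepts slows mixing of intercepts only and
never touches β_int; keeping the sampler purely conjugate makes it
exactly checkable against a quadrature oracle. Default schedule: 4
chains × 250 retained draws, thinning 10, burn-in 500 — a desk-scale
schedule; heavier thinning (e.g. 1000) is available through
`MCMCSettings` for production-scale runs.

### Diagnostics

PSRF (Gelman–Rubin) is computed per species-level coefficient as
sqrt(((n−1)/n·W + B/n)/W); a run is flagged non-converged when any value
exceeds 1.1. The raw formula gives sqrt((n−1)/n) < 1 for identical
chains, so values are floored at 1.0 — a between-chain variance smaller
than the within-chain variance carries no convergence information. Zero
within-chain variance with unequal means returns +∞. Fit metrics use
posterior-mean occurrence probabilities: AUC (rank statistic, ties count
1/2), Tjur R² = mean(p̂ | y=1) − mean(p̂ | y=0), RMSE. Species observed
in a single class get missing metrics.

## Classification

Support = max(P(β_int > 0), P(β_int < 0)) over the pooled posterior
draws; a species is positive/negative when support ≥ 0.90 (the boundary
is inclusive: only responses with less than 90% posterior probability
are discarded), else none. Constant draws classify by sign with support
1. The six-way process category compares posterior-mean slopes outside
(β_year) and inside (β_year + β_int) PAs; the support requirement
applies only to β_int — using posterior-mean slopes for the sign
determination (rather than joint posterior sign events) is a package
decision. Exactly zero mean slopes are tie-broken as non-negative and
logged. Moderator analyses (PAs above the median size, the
post-establishment year window, the strictest IUCN category present,
excluding the North Boreal stratum) always keep matched pairs together
and refit the full model on the subset rather than reusing the main
posterior; in the post-establishment window each control is trimmed to
the same years as its treated partner, so pairs stay comparable.

## Traits and phylogenetic signal

Per-taxon OLS of the per-species effect (posterior mean of β_int) on
log body size, species temperature index and threat status, with
predictors restricted per taxon (no threat status for plants; only body
size for phytoplankton, whose STI is unavailable). Rank-deficient
designs error out naming the collinear columns; outputs include the
predictor correlation matrix and a Shapiro–Wilk residual-normality
summary. Missing traits are flagged and excluded, never imputed.
Phylogenetic GLS is deliberately not used — the trait models are
ordinary regressions, and signal is tested separately.

Blomberg's K is the observed MSE0/MSE ratio over its Brownian-motion
expectation on the same tree (K ≈ 1 under BM); significance via 999
seeded tip-label permutations (the permutation test is a package choice;
the statistic's source does not fix a test). Pagel's λ scales the
off-diagonal phylogenetic covariance; the MLE is found by bounded 1-D
search on [0, 1] (tolerance 1e-6) with explicit endpoint checks, and
boundary optima are reported with a warning, never truncated silently.
Tips without effect values (e.g. species dropped by the record filter)
are pruned from the covariance. Both statistics are affine-invariant in
the trait, and λ = 0 reproduces the star-phylogeny likelihood exactly —
both properties are under test.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not Finnish geography: a 100 × 100 km planar landscape split into three
latitude bands (HSB/MB/NB); per-site land-cover proportions from
zone-specific Dirichlet draws (8 classes + a residual class, so
proportions sum to ≤ 1); survey geometries and efforts per scheme
profile (3–6 km two-leg transects, 4-km-side triangles, points, lakes
with lognormal areas and 4 lake covariates). PA placement probability is
expit(logit(0.35) + b·z(artificial cover) + 0.5·b·1[NB]) with
b = `pa_placement_bias` (so b = 0 is completely random placement), and
PA sizes are lognormal with a 6× multiplier in the North Boreal zone —
reproducing the northern bias of real reserve networks.

Species: intercepts N(baseline_mean, baseline_sd²), year slopes
N(0, trend_sd²), and a spike-and-slab interaction — zero with
probability 1 − `prop_effect_nonzero`, else N(0, effect_sd²). Occurrence
is generated directly as Bernoulli(Φ(linear predictor) ×
detection_per_visit) on the same design the fitter uses (year 1 =
earliest survey year), since the analysis converts abundance to
occurrence before modelling anyway. Unbalanced revisit calendars thin
site-years with retention probability `revisit_prob` (every site keeps
at least one year). Random streams are split per operation
(landscape/community/calendar/occurrence), so changing `n_years` never
perturbs the landscape. The phylogeny is a pure-birth tree conditioned
by the general sampling approach (no zero-length pendant edges); log
body size evolves under Brownian motion on it, STI is drawn
independently of the tree, threat status is Bernoulli(0.2).

Default magnitudes (effect_sd 0.05 probit/yr, 30% nonzero, site RE 0.3,
year RE 0.1) are chosen for statistical detectability at desk scale —
real protection effects on the probit scale are not established in the
literature — and are fixed study conditions, not tuning knobs.

What passing tests do and do not show: the generator has no spatial
autocorrelation beyond the shared site intercept, no observation-process
structure beyond a per-visit detection scalar, no species interactions,
and covariates that affect PA placement but not occupancy. Recovery and
calibration results therefore validate the machinery — they do not
certify performance on real monitoring data, where residual confounding
and richer dependence structures are possible.

## Evaluation experiments

`paimpact.benchmarks` packages the evaluation battery (also run by
`scripts/acceptance.py` and the acceptance tests), at these problem
sizes: sampler-vs-quadrature on 5 presences/5 absences with a N(0, 25)
prior; recovery over 3 replicate seeds of 60 species × 300 matched
sites × 20 years with 2 chains × 250 retained draws (thin 2, burn 300);
null calibration with 200 zero-effect species; 100 balance replicates
of 200-site landscapes; 50 matching instances vs a brute-force greedy
reference; 200 64-tip trees for K and 100 128-tip replicates for λ. The
pipeline smoke configuration is 100 sites × 30 species × 10 years with
2 chains × 200 draws.

## Numerical choices and degenerate inputs

- Truncated-normal draws clip CDF arguments at 1e-15 and force the sign
  implied by the response; linear predictors are checked finite every
  iteration and abort with the offending unit/species named.
- Pooled covariances get a 1e-8 ridge before Cholesky; a matrix still
  singular after the ridge is an error.
- SMD with zero pooled SD is 0 when the means agree, +∞ otherwise.
- An empty control pool in a stratum drops that stratum's treated units
  with a warning; an empty moderator subset, an empty post-establishment
  window, and a species table emptied by the <10-record filter are all
  hard errors with counts in the message.
- Tie-breaks are deterministic everywhere (site-id order in matching,
  non-negative slopes in process classification), making byte-identical
  reruns a tested contract.

## Known limitations

No spatial latent factors or covariance kernels; no abundance models;
no matching with replacement or many-to-one designs; no reprojection
(inputs must share a planar metre CRS); no figure reproduction beyond
plain data exports; λ is restricted to [0, 1] rather than the tree's
maximal feasible value.
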