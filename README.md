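# paimpact

Counterfactual impact evaluation of protected areas (PAs) on multispecies
occupancy trends, as a tested, reusable pipeline.

Whether area-based protection actually slows local biodiversity loss is
hard to answer from monitoring data alone: PAs are placed non-randomly
(in the north, on unproductive land), so naive protected-vs-unprotected
comparisons confound protection with geography and habitat. `paimpact`
implements the counterfactual workflow used in multi-taxon PA
assessments — every step from raw occurrence records to per-species
response classes — and ships a synthetic-data generator with known ground
truth so the whole chain can be validated end to end:

1. **Protection assignment** (`geoassign`): taxon-specific buffers
   (500 m around bird line transects, a disc extending 500 m beyond
   wildlife-triangle vertices, 100 m around plant plots, the lake polygon
   itself for phytoplankton) intersected with PA polygons; PA size, IUCN
   category and establishment year attributed from the largest overlap.
2. **Matched design** (`matching`): one-to-one greedy nearest-neighbour
   matching without replacement, propensity-score or Mahalanobis
   distance, caliper 0.25 SD of the propensity scores, exact
   vegetation-zone strata, standardized-mean-difference balance
   diagnostics, and per-dataset method selection by balance.
3. **Trend model** (`trendmodel`): a hierarchical Bayesian multispecies
   probit model,

       P(y_uj = 1) = Φ(β0_j + β_year,j·t + β_int,j·t·protected + zone + log-effort + a_site + b_year)

   with community-level pooling β_j ~ N(μ, V) and exchangeable site/year
   random intercepts, fitted by a Gibbs sampler with latent-utility data
   augmentation; PSRF convergence diagnostics, AUC / Tjur R² / RMSE fit
   metrics. The year index t is rescaled so year 1 is the earliest survey
   year, and **β_int — the protection × year interaction — is the causal
   estimand**: the difference in occupancy trend attributable to
   protection.
4. **Classification** (`classify`): a species responds when
   P(β_int > 0) or P(β_int < 0) ≥ 0.90; responders are sorted into the
   six processes by which protection can reshape a trend (alleviated /
   accelerated declines and increases, inversions in either direction);
   moderator re-analyses restrict the design to large PAs,
   post-establishment years, the strictest IUCN class, or exclude the
   North Boreal zone.
5. **Traits & phylogeny** (`traitsphylo`): per-taxon OLS of effects on
   log body size, species temperature index and threat status;
   phylogenetic signal via Blomberg's K (permutation test) and
   maximum-likelihood Pagel's λ.
6. **Synthetic data** (`synthdata`): landscapes with 8 land-cover
   proportions per site, three vegetation zones, biased PA placement,
   spike-and-slab protection effects, unbalanced revisit calendars,
   Brownian-motion traits on a simulated phylogeny — plus the full
   generative truth for recovery tests.

## Worked example

`examples/` holds one short script per capability. Building the matched
design on a simulated landscape (`examples/02_match_sites.py`) prints:

```
method selected: mahalanobis
matched 139 of 223 protected sites (62%)

balance (absolute SMD):
       covariate  smd_before  smd_after
      artificial       0.455      0.139
         wetland       0.096      0.016
           water       0.037      0.005
          arable       0.036      0.001
      shrub_herb       0.082      0.062
       broadleaf       0.022      0.022
         conifer       0.246      0.026
    mixed_forest       0.053      0.004
mean_survey_year       0.000      0.000
          effort       0.003      0.112

mean |SMD| after matching: 0.039 (< 0.1 is conventionally called balanced)
```

The biased PA placement shows up as a strong pre-matching imbalance on
artificial and coniferous cover (SMD 0.46 and 0.25); after matching the
mean |SMD| drops to 0.04, i.e. the paired protected and unprotected
sites are environmentally comparable. Fitting the trend model and
classifying responses (`examples/04_classify_responses.py`) then prints:

```
25 species: 20% positive, 24% negative, 56% no detectable response

responding species:
species_id  effect_mean  support response_class     process_category
     sp004        0.115    1.000       positive accelerated_increase
     sp005        0.042    0.956       positive   alleviated_decline
     ...
```

`effect_mean` is the posterior mean of β_int (probit units/year),
`support` the posterior probability of its sign; `sp005` declines both
inside and outside PAs but more slowly inside — protection alleviates
its decline.

The same workflow runs from the shell:

```bash
paimpact run-all --config config.yaml --out run --seed 11
```

## Layout

```
src/paimpact/     config, synthdata, geoassign, matching, trendmodel,
                  classify, traitsphylo, io, pipeline, benchmarks, cli
examples/         one narrative script per capability
tests/            unit, property and acceptance suites
docs/methods.md   model, priors, generator and design notes
```
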