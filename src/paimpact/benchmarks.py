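"""Simulation experiments that quantify end-to-end statistical performance.

Each function regenerates its own synthetic data from a seed, runs the
relevant part of the pipeline and returns summary numbers: parameter
recovery and credible-interval coverage for the protection x year effect,
false-response rates under a null community, covariate-balance improvement
from matching, PSRF behaviour on known chains, and phylogenetic-signal
statistics under Brownian motion and under independence.  Problem sizes
default to desk scale (hundreds of sites/species, minutes of CPU).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr
from shapely.geometry import Point, Polygon

from . import io, matching, synthdata, trendmodel
from .classify import classify_species
from .config import MCMCSettings, SimulationConfig
from .geoassign import ProtectedArea, SurveySite, assign_protection, build_buffer
from .pipeline import simulate_matched_dataset
from .traitsphylo import blomberg_k, pagel_lambda
from .trendmodel import Priors, fit, psrf


def _recovery_mcmc(seed: int) -> MCMCSettings:
    return MCMCSettings(n_chains=2, n_burn=300, n_thin=2, n_retain=250, seed=seed)


def sampler_oracle_check(seed: int = 1) -> dict:
    """Single-species intercept-only probit posterior vs 1-D quadrature.

    Returns the Gibbs posterior mean of Phi(beta0) for 5 presences and 5
    absences under a N(0, 25) prior, the exact value by grid integration,
    and a batch-means Monte-Carlo SE.
    """
    n_pres = n_abs = 5
    design = trendmodel.TrendDesign(
        Y=np.r_[np.ones(n_pres), np.zeros(n_abs)].reshape(-1, 1),
        X=np.ones((n_pres + n_abs, 1)),
        colnames=["intercept"],
        site_index=np.zeros(n_pres + n_abs, dtype=int),
        year_index=np.zeros(n_pres + n_abs, dtype=int),
        site_ids=["s1"],
        years=[2000],
        species_ids=["sp1"],
        has_year_re=False,
        year0=2000,
    )
    mcmc = MCMCSettings(n_chains=2, n_burn=200, n_thin=2, n_retain=1000, seed=seed)
    f = fit(design, mcmc, Priors(mu0=np.zeros(1), fixed_v=np.array([[25.0]])),
            include_site_re=False, include_year_re=False)
    draws = ndtr(f.beta_draws("intercept")[:, 0])
    grid = np.linspace(-8, 8, 40001)
    p = ndtr(grid)
    log_post = n_pres * np.log(p) + n_abs * np.log1p(-p) - 0.5 * grid**2 / 25.0
    w = np.exp(log_post - log_post.max())
    exact = float((w * p).sum() / w.sum())
    batches = draws.reshape(2, 20, -1).mean(axis=2)
    se = float(batches.std(ddof=1) / math.sqrt(batches.size))
    return {"gibbs_mean": float(draws.mean()), "quadrature_mean": exact, "mc_se": se,
            "n_draws": int(draws.size)}


def recovery_experiment(
    seed: int = 1,
    n_seeds: int = 3,
    n_sites: int = 600,
    n_species: int = 60,
    n_years: int = 20,
    max_pairs: int = 150,
) -> dict:
    """Spike-and-slab recovery of the protection x year interaction.

    For each replicate seed: simulate a landscape, build the matched
    design (300 matched sites by default), fit the trend model and compare
    posterior means / 90% credible intervals of beta_int with the
    generator's truth.
    """
    rs, covered, null_means = [], [], []
    for k in range(n_seeds):
        s = seed + k
        sim = SimulationConfig(n_sites=n_sites, n_species=n_species, n_years=n_years, seed=s)
        data = simulate_matched_dataset(sim, max_pairs=max_pairs)
        f = fit(data["trend_design"], _recovery_mcmc(s), Priors())
        draws = f.beta_draws("prot_x_year")
        pm = draws.mean(axis=0)
        lo = np.quantile(draws, 0.05, axis=0)
        hi = np.quantile(draws, 0.95, axis=0)
        truth = data["truth"]
        idx = [truth.species_ids.index(sp) for sp in f.species_ids]
        tr = truth.beta_int[idx]
        rs.append(float(np.corrcoef(tr, pm)[0, 1]))
        covered.append((tr >= lo) & (tr <= hi))
        null_means.append(pm[tr == 0])
    allc = np.concatenate(covered)
    return {
        "r_per_seed": rs,
        "pearson_r_min": float(min(rs)),
        "pearson_r_mean": float(np.mean(rs)),
        "ci90_coverage": float(allc.mean()),
        "null_effect_bias": float(np.concatenate(null_means).mean()),
        "n_species_total": int(allc.size),
        "n_matched_sites": 2 * max_pairs,
    }


def null_calibration_experiment(
    seed: int = 1,
    n_species: int = 200,
    n_sites: int = 250,
    n_years: int = 12,
    threshold: float = 0.90,
) -> dict:
    """False-response rate when every true interaction effect is zero."""
    sim = SimulationConfig(
        n_sites=n_sites, n_species=n_species, n_years=n_years,
        prop_effect_nonzero=0.0, seed=seed,
    )
    data = simulate_matched_dataset(sim)
    f = fit(data["trend_design"], _recovery_mcmc(seed), Priors())
    responses = classify_species(
        f.beta_draws("prot_x_year"), f.beta_draws("year_rescaled"), f.species_ids, threshold
    )
    non_none = (responses["response_class"] != "none").mean()
    n = len(responses)
    return {
        "non_none_rate": float(non_none),
        "n_species": int(n),
        "threshold": threshold,
        "bound": 2 * (1 - threshold) + 3 * math.sqrt(0.2 * 0.8 / n),
    }


def balance_experiment(seed: int = 1, n_reps: int = 100, n_sites: int = 200) -> dict:
    """Does matching improve covariate balance under biased PA placement?"""
    improved = 0
    befores, afters = [], []
    for k in range(n_reps):
        sim = SimulationConfig(n_sites=n_sites, n_species=3, pa_placement_bias=1.0, seed=seed + k)
        sites, pas = synthdata.generate_landscape(sim)
        from .geoassign import protection_table

        prot = protection_table(sites, pas)
        frame = io.sites_frame(sites).merge(prot[["site_id", "protected"]], on="site_id")
        design = matching.build_matched_design(frame, sim.taxon_group)
        before = float(design.balance["smd_before"].abs().mean())
        after = float(design.balance["smd_after"].abs().mean())
        befores.append(before)
        afters.append(after)
        improved += after <= before
    return {
        "frac_improved": improved / n_reps,
        "mean_smd_before": float(np.mean(befores)),
        "mean_smd_after": float(np.mean(afters)),
        "n_reps": n_reps,
    }


def matching_oracle_experiment(seed: int = 1, n_draws: int = 50) -> dict:
    """Exhaustive agreement of greedy matching with a brute-force
    sequential-greedy reference on small single-stratum instances."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_draws):
        nt = int(rng.integers(1, 7))
        nc = int(rng.integers(1, 7))
        scores_arr = np.round(rng.uniform(0.05, 0.95, nt + nc), 3)
        ids = [f"S{i:03d}" for i in range(nt + nc)]
        frame = pd.DataFrame(
            {"site_id": ids, "protected": [True] * nt + [False] * nc,
             "vegetation_zone": ["MB"] * (nt + nc)}
        )
        scores = pd.Series(scores_arr, index=ids)
        design = matching.greedy_match(frame, scores, caliper_multiplier=0.25)
        caliper = 0.25 * scores.std(ddof=1)
        expect = _reference_greedy(
            {s: scores[s] for s in ids[:nt]}, {s: scores[s] for s in ids[nt:]}, caliper
        )
        ok = design.pairs == expect
        controls = [c for _, c in design.pairs]
        ok &= len(controls) == len(set(controls))
        ok &= all(abs(scores[t] - scores[c]) <= caliper for t, c in design.pairs)
        agree += ok
    return {"agreement_rate": agree / n_draws, "n_instances": n_draws}


def _reference_greedy(treated_scores, control_scores, caliper):
    """Independently coded brute-force reference: descending treated score,
    nearest unused control within the caliper, index tie-breaks."""
    order = sorted(treated_scores, key=lambda k: (-treated_scores[k], k))
    available = dict(control_scores)
    pairs = []
    for t in order:
        best, best_d = None, None
        for c in sorted(available):
            d = abs(treated_scores[t] - available[c])
            if d > caliper:
                continue
            if best_d is None or d < best_d:
                best, best_d = c, d
        if best is not None:
            pairs.append((t, best))
            del available[best]
    return pairs


def psrf_experiment(seed: int = 1, n_reps: int = 100, n_draws: int = 1000) -> dict:
    """PSRF on chains with known relationships: identical copies, two
    independent chains from one stationary normal, and divergent means."""
    rng = np.random.default_rng(seed)
    chain = rng.normal(size=n_draws)
    identical = psrf(np.vstack([chain, chain]))
    below = sum(
        psrf(rng.normal(size=(2, n_draws))) < 1.1 for _ in range(n_reps)
    )
    divergent = min(
        psrf(np.vstack([rng.normal(0, 1, n_draws), rng.normal(10, 1, n_draws)]))
        for _ in range(20)
    )
    return {
        "identical_chains": float(identical),
        "frac_stationary_below_1p1": below / n_reps,
        "min_divergent": float(divergent),
    }


def halfplane_coverage_check(r: float = 100.0, d: float = 30.0) -> dict:
    """Circle/half-plane coverage: package geometry vs the analytic
    circular-segment area."""
    site = SurveySite(
        site_id="s1", taxon_group="plants", geometry=Point(0.0, 0.0),
        vegetation_zone="MB", covariates=np.full(8, 0.1),
        mean_survey_year=2005.0, effort=1.0,
    )
    buf = build_buffer(site)
    pa = ProtectedArea(
        pa_id="PA1",
        polygon=Polygon([(d, -50 * r), (100 * r, -50 * r), (100 * r, 50 * r), (d, 50 * r)]),
        size_ha=1.0, iucn_category="II", year_established=1990,
    )
    _, cov, _ = assign_protection(site, buf, [pa])
    analytic = (r**2 * math.acos(d / r) - d * math.sqrt(r**2 - d**2)) / (math.pi * r**2)
    return {"coverage": float(cov), "analytic": analytic, "abs_error": abs(cov - analytic)}


def signal_experiment(
    seed: int = 1, n_trees_k: int = 200, n_tips_k: int = 64,
    n_reps_lambda: int = 100, n_tips_lambda: int = 128,
) -> dict:
    """Blomberg's K and Pagel's lambda under Brownian motion and under
    tree-independent traits, on replicate pure-birth trees."""
    rng = np.random.default_rng(seed)

    def bm(newick):
        V, labels = synthdata.tree_vcv(newick)
        x = np.linalg.cholesky(V + 1e-10 * np.eye(len(V))) @ rng.standard_normal(len(V))
        return pd.Series(x, index=labels), labels

    ks = []
    for k in range(n_trees_k):
        nwk = synthdata.simulate_tree(n_tips_k, seed * 10_000 + k)
        x, _ = bm(nwk)
        ks.append(blomberg_k(nwk, x, n_permutations=0, seed=k)[0])
    lams_bm, lams_null = [], []
    for k in range(n_reps_lambda):
        nwk = synthdata.simulate_tree(n_tips_lambda, seed * 20_000 + k)
        x, labels = bm(nwk)
        lams_bm.append(pagel_lambda(nwk, x)[0])
        indep = pd.Series(rng.standard_normal(len(labels)), index=labels)
        lams_null.append(pagel_lambda(nwk, indep)[0])
    return {
        "blomberg_k_bm_mean": float(np.mean(ks)),
        "pagel_lambda_bm_mean": float(np.mean(lams_bm)),
        "pagel_lambda_indep_median": float(np.median(lams_null)),
        "n_trees_k": n_trees_k,
        "n_reps_lambda": n_reps_lambda,
    }
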