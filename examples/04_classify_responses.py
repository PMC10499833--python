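"""Classify species responses to protection from the posterior.

A species responds when P(b_int > 0) or P(b_int < 0) reaches 90%; the
responders are then sorted into the six processes by which protection can
reshape a trend (alleviated/accelerated declines or increases, and trend
inversions), from the posterior-mean slopes outside vs inside PAs.
"""

from paimpact import (
    MCMCSettings,
    SimulationConfig,
    aggregate,
    classify_species,
    fit,
    simulate_matched_dataset,
)

sim = SimulationConfig(n_sites=300, n_species=25, n_years=15, effect_sd=0.08, seed=7)
data = simulate_matched_dataset(sim, max_pairs=75)
f = fit(data["trend_design"], MCMCSettings(n_chains=2, n_burn=200, n_thin=2, n_retain=250, seed=7))

responses = classify_species(
    f.beta_draws("prot_x_year"), f.beta_draws("year_rescaled"), f.species_ids, threshold=0.90
)
summary = aggregate(responses).iloc[0]
print(f"{summary['n_species']} species: "
      f"{summary['pct_positive']:.0f}% positive, {summary['pct_negative']:.0f}% negative, "
      f"{summary['pct_none']:.0f}% no detectable response")
print("\nprocess categories among responders:")
counts = responses.loc[responses.response_class != "none", "process_category"].value_counts()
print(counts.to_string() if len(counts) else "(none)")
print("\nresponding species:")
cols = ["species_id", "effect_mean", "support", "response_class", "process_category"]
print(responses.loc[responses.response_class != "none", cols].round(3).to_string(index=False))
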