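"""Generator contracts: determinism, proportions, mixture calibration and
agreement between simulated frequencies and the analytic probit model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from paimpact import (
    SimulationConfig,
    generate_community,
    generate_landscape,
    protection_table,
    sample_calendar,
    simulate_occurrences,
    tree_vcv,
)
from paimpact import io as pio
from paimpact.synthdata import simulate_tree, standardized_log_effort


def _occurrence_run(config):
    sites, pas = generate_landscape(config)
    prot = protection_table(sites, pas)
    truth, _, _ = generate_community(config, tree_seed=123)
    records = simulate_occurrences(sites, truth, config, prot)
    return sites, pas, prot, truth, records


class TestDeterminism:
    def test_identical_seed_identical_outputs(self, small_config):
        a = _occurrence_run(small_config)
        b = _occurrence_run(small_config)
        pd.testing.assert_frame_equal(pio.sites_frame(a[0]), pio.sites_frame(b[0]))
        assert [s.geometry.wkt for s in a[0]] == [s.geometry.wkt for s in b[0]]
        assert [p.polygon.wkt for p in a[1]] == [p.polygon.wkt for p in b[1]]
        pd.testing.assert_frame_equal(a[4], b[4])

    def test_landscape_unchanged_by_n_years(self, small_config):
        other = SimulationConfig(**{**small_config.to_dict(), "n_years": 3})
        a, _ = generate_landscape(small_config)
        b, _ = generate_landscape(other)
        assert [s.geometry.wkt for s in a] == [s.geometry.wkt for s in b]


class TestLandscape:
    def test_covariates_are_proportions(self, small_landscape):
        for s in small_landscape[0]:
            assert np.all(s.covariates >= 0) and np.all(s.covariates <= 1)
            assert s.covariates.sum() <= 1 + 1e-12
            assert s.vegetation_zone in ("HSB", "MB", "NB")

    def test_unbiased_placement_uncorrelated_with_covariates(self):
        config = SimulationConfig(n_sites=2000, n_species=3, pa_placement_bias=0.0, seed=5)
        sites, pas = generate_landscape(config)
        prot = protection_table(sites, pas).set_index("site_id")["protected"].astype(float)
        frame = pio.sites_frame(sites).set_index("site_id")
        from paimpact.synthdata import COVARIATE_NAMES

        for cov in COVARIATE_NAMES:
            r = np.corrcoef(prot.to_numpy(), frame[cov].to_numpy())[0, 1]
            assert abs(r) < 3.5 / np.sqrt(len(prot))

    def test_biased_placement_correlates_with_designated_covariate(self):
        config = SimulationConfig(n_sites=2000, n_species=3, pa_placement_bias=1.5, seed=5)
        sites, pas = generate_landscape(config)
        prot = protection_table(sites, pas).set_index("site_id")["protected"].astype(float)
        frame = pio.sites_frame(sites).set_index("site_id")
        assert np.corrcoef(prot.to_numpy(), frame["artificial"].to_numpy())[0, 1] > 0.05

    def test_nonfinite_bias_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SimulationConfig(pa_placement_bias=float("nan"))

    def test_nb_pas_larger(self):
        config = SimulationConfig(n_sites=1200, n_species=3, seed=2)
        sites, pas = generate_landscape(config)
        # PAs seeded in NB (top band) vs elsewhere
        nb = [p.size_ha for p in pas if p.polygon.centroid.y > 0.80 * 100_000]
        south = [p.size_ha for p in pas if p.polygon.centroid.y <= 0.80 * 100_000]
        assert np.median(nb) > 2 * np.median(south)


class TestCommunity:
    def test_spike_only(self):
        config = SimulationConfig(n_species=50, prop_effect_nonzero=0.0)
        truth, _, _ = generate_community(config, tree_seed=1)
        assert np.all(truth.beta_int == 0)

    def test_slab_sd_matches_direct_resampling_oracle(self):
        config = SimulationConfig(n_species=500, prop_effect_nonzero=1.0, effect_sd=0.05)
        truth, _, _ = generate_community(config, tree_seed=1)
        # oracle: SE of a sample SD of N(0, 0.05^2), n=500, by direct resampling
        rng = np.random.default_rng(0)
        sds = [rng.normal(0, 0.05, 500).std(ddof=1) for _ in range(400)]
        assert abs(truth.beta_int.std(ddof=1) - 0.05) < 4 * np.std(sds)

    def test_mixture_calibration(self):
        config = SimulationConfig(n_species=400, prop_effect_nonzero=0.3, seed=9)
        truth, _, _ = generate_community(config, tree_seed=3)
        frac = (truth.beta_int != 0).mean()
        se = np.sqrt(0.3 * 0.7 / 400)
        assert abs(frac - 0.3) <= 3 * se

    def test_tree_is_ultrametric_with_right_tips(self):
        newick = simulate_tree(32, seed=11)
        V, labels = tree_vcv(newick)
        assert len(labels) == 32
        depths = np.diag(V)
        assert np.allclose(depths, depths[0], rtol=1e-8)
        assert np.all(np.linalg.eigvalsh(V) > -1e-9)

    def test_minimum_species(self):
        with pytest.raises(ValueError, match="3 species"):
            generate_community(SimulationConfig(n_species=2), tree_seed=1)


class TestOccurrences:
    def test_probit_identity_all_zero_coefficients(self):
        config = SimulationConfig(
            n_sites=40, n_species=25, n_years=12, baseline_mean=0.0, baseline_sd=0.0,
            trend_sd=0.0, effect_sd=0.0, site_re_sd=0.0, year_re_sd=0.0, seed=3,
        )
        sites, pas, prot, truth, records = _occurrence_run(config)
        truth.zone_offsets[:] = 0.0
        truth.effort_coef[:] = 0.0
        records = simulate_occurrences(sites, truth, config, prot)
        n = len(records)
        assert abs(records["occ"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_interaction_cancels_trend_inside_pas(self):
        # beta_int = -beta_year: expected occupancy is flat inside PAs while
        # it declines outside — checked on exact probabilities
        t = np.arange(1, 21)
        beta0, beta_year = 0.2, -0.05
        outside = ndtr(beta0 + beta_year * t)
        inside = ndtr(beta0 + beta_year * t + (-beta_year) * t)
        assert np.allclose(inside, ndtr(beta0))
        assert outside[-1] < outside[0]

    def test_empirical_frequencies_match_analytic_probabilities(self):
        config = SimulationConfig(
            n_sites=5, n_species=3, n_years=500, trend_sd=0.0, year_re_sd=0.0,
            revisit_prob=1.0, seed=21,
        )
        sites, pas = generate_landscape(config)
        prot = protection_table(sites, pas)
        truth, _, _ = generate_community(config, tree_seed=4)
        truth.beta_year[:] = 0.0
        truth.beta_int[:] = 0.0
        records = simulate_occurrences(sites, truth, config, prot)
        z_eff = standardized_log_effort(pd.Series({s.site_id: s.effort for s in sites}))
        zone_col = {"HSB": None, "MB": 0, "NB": 1}
        for s in sites:
            for j, sp in enumerate(truth.species_ids):
                zi = zone_col[s.vegetation_zone]
                lp = (
                    truth.beta0[j]
                    + (truth.zone_offsets[j, zi] if zi is not None else 0.0)
                    + truth.effort_coef[j] * z_eff[s.site_id]
                    + truth.site_re[s.site_id]
                )
                p = float(ndtr(lp))
                sub = records[(records.site_id == s.site_id) & (records.species_id == sp)]
                se = np.sqrt(max(p * (1 - p), 1e-6) / len(sub))
                assert abs(sub["occ"].mean() - p) <= 4 * se

    def test_mean_records_only_for_sampled_site_years(self, small_config):
        sites, pas = generate_landscape(small_config)
        prot = protection_table(sites, pas)
        truth, _, _ = generate_community(small_config, tree_seed=1)
        cal = sample_calendar(small_config, [s.site_id for s in sites])
        records = simulate_occurrences(sites, truth, small_config, prot, cal)
        got = set(map(tuple, records[["site_id", "year"]].drop_duplicates().to_numpy()))
        want = set(map(tuple, cal.to_numpy()))
        assert got == want

    def test_nonfinite_linear_predictor_refused(self, small_config):
        sites, pas = generate_landscape(small_config)
        prot = protection_table(sites, pas)
        truth, _, _ = generate_community(small_config, tree_seed=1)
        truth.beta0[0] = np.inf
        with pytest.raises(FloatingPointError, match="non-finite"):
            simulate_occurrences(sites, truth, small_config, prot)
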