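"""Gibbs sampler correctness, design construction and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from paimpact import (
    MCMCSettings,
    Priors,
    TrendDesign,
    build_design,
    filter_species,
    fit,
    fit_metrics,
    psrf,
)
from paimpact.trendmodel import binary_metrics


def intercept_only_design(n_pres: int, n_abs: int) -> TrendDesign:
    n = n_pres + n_abs
    return TrendDesign(
        Y=np.r_[np.ones(n_pres), np.zeros(n_abs)].reshape(-1, 1),
        X=np.ones((n, 1)),
        colnames=["intercept"],
        site_index=np.zeros(n, dtype=int),
        year_index=np.zeros(n, dtype=int),
        site_ids=["s1"],
        years=[2000],
        species_ids=["sp1"],
        has_year_re=False,
        year0=2000,
    )


def quadrature_posterior_mean_phi(n_pres: int, n_abs: int, prior_var: float) -> float:
    """1-D grid integration of the exact single-species probit posterior."""
    grid = np.linspace(-8, 8, 40001)
    p = ndtr(grid)
    log_post = (
        n_pres * np.log(p)
        + n_abs * np.log1p(-p)
        - 0.5 * grid**2 / prior_var
    )
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    return float((w * p).sum())


def _records(rows):
    return pd.DataFrame(rows, columns=["site_id", "species_id", "year", "occ", "effort"])


class TestFilterSpecies:
    def test_boundary_at_ten_presences(self):
        rows = []
        for i in range(12):
            rows.append(("s1", "rare", 2000 + i, int(i < 9), 1.0))
            rows.append(("s1", "common", 2000 + i, int(i < 10), 1.0))
            rows.append(("s1", "absent", 2000 + i, 0, 1.0))
        out = filter_species(_records(rows))
        assert set(out["species_id"]) == {"common"}

    def test_empty_result_is_an_error(self):
        rows = [("s1", "sp1", 2000, 0, 1.0)]
        with pytest.raises(ValueError, match="simulate more data"):
            filter_species(_records(rows))


class TestBuildDesign:
    def _inputs(self):
        rows = []
        for sid, protected in (("s1", True), ("s2", False)):
            for y in (1989, 1995, 2000):
                for sp in ("spA", "spB"):
                    rows.append((sid, sp, y, 1, 2.0))
        records = _records(rows)
        protection = pd.DataFrame(
            {
                "site_id": ["s1", "s2"],
                "protected": [True, False],
                "year_established": [1995, -1],
                "size_ha": [50.0, np.nan],
                "iucn_cat": ["II", ""],
            }
        )
        zones = pd.Series({"s1": "MB", "s2": "MB"})
        return records, protection, zones

    def test_earliest_year_maps_to_one(self):
        records, protection, zones = self._inputs()
        d = build_design(records, protection, zones)
        t = d.X[:, d.colnames.index("year_rescaled")]
        assert d.year0 == 1989 and t.min() == 1.0 and t.max() == 12.0

    def test_interaction_is_elementwise_product(self):
        records, protection, zones = self._inputs()
        d = build_design(records, protection, zones)
        prot = d.X[:, d.colnames.index("protected")]
        t = d.X[:, d.colnames.index("year_rescaled")]
        inter = d.X[:, d.colnames.index("prot_x_year")]
        assert np.array_equal(inter, prot * t)
        # unprotected site rows have an all-zero interaction column
        assert np.all(inter[prot == 0] == 0)

    def test_post_establishment_window_trims_pair_together(self):
        records, protection, zones = self._inputs()
        d = build_design(
            records, protection, zones,
            subset_window="post_establishment", pairs=[("s1", "s2")],
        )
        years = {d.years[i] for i in d.year_index}
        assert years == {1995, 2000}  # 1989 dropped for s1 AND its control s2
        assert d.year0 == 1995

    def test_missing_zone_rejected(self):
        records, protection, _ = self._inputs()
        with pytest.raises(ValueError, match="zone"):
            build_design(records, protection, pd.Series({"s1": "MB"}))

    def test_year_re_toggle_for_plants(self):
        records, protection, zones = self._inputs()
        d = build_design(records, protection, zones, include_year_re=False)
        assert d.has_year_re is False


class TestSampler:
    def test_posterior_matches_quadrature_oracle(self):
        design = intercept_only_design(5, 5)
        mcmc = MCMCSettings(n_chains=2, n_burn=200, n_thin=2, n_retain=1000, seed=4)
        f = fit(design, mcmc, Priors(mu0=np.zeros(1), fixed_v=np.array([[25.0]])),
                include_site_re=False, include_year_re=False)
        draws = ndtr(f.beta_draws("intercept")[:, 0])
        exact = quadrature_posterior_mean_phi(5, 5, 25.0)
        # Monte-Carlo SE from per-chain batch means
        per_chain = draws.reshape(2, -1)
        batches = per_chain.reshape(2, 20, -1).mean(axis=2)
        se = batches.std(ddof=1) / np.sqrt(batches.size)
        assert abs(draws.mean() - exact) < 3 * max(se, 1e-4)

    def test_identical_seeds_give_identical_draws(self):
        design = intercept_only_design(6, 4)
        mcmc = MCMCSettings(n_chains=2, n_burn=50, n_thin=1, n_retain=50, seed=9)
        f1 = fit(design, mcmc)
        f2 = fit(design, mcmc)
        assert np.array_equal(f1.beta, f2.beta)

    def test_label_symmetry(self):
        rng = np.random.default_rng(2)
        n, S = 200, 4
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        B0 = rng.normal(0, 0.5, size=(2, S))
        Y = (rng.uniform(size=(n, S)) < ndtr(X @ B0)).astype(float)

        def make(Ymat):
            return TrendDesign(
                Y=Ymat, X=X, colnames=["intercept", "x"],
                site_index=np.zeros(n, int), year_index=np.zeros(n, int),
                site_ids=["s1"], years=[2000], species_ids=[f"sp{j}" for j in range(S)],
                has_year_re=False, year0=2000,
            )

        mcmc = MCMCSettings(n_chains=2, n_burn=200, n_thin=1, n_retain=300, seed=5)
        kw = dict(include_site_re=False, include_year_re=False)
        f_pos = fit(make(Y), mcmc, **kw)
        f_neg = fit(make(1.0 - Y), mcmc, **kw)
        m_pos = f_pos.beta_draws("x").mean(axis=0)
        m_neg = f_neg.beta_draws("x").mean(axis=0)
        assert np.allclose(m_pos, -m_neg, atol=0.12)

    def test_shrinkage_direction_with_small_community_variance(self):
        rng = np.random.default_rng(8)
        n, S = 150, 8
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        B0 = np.vstack([np.zeros(S), rng.normal(0, 1.0, S)])
        Y = (rng.uniform(size=(n, S)) < ndtr(X @ B0)).astype(float)
        design = TrendDesign(
            Y=Y, X=X, colnames=["intercept", "x"],
            site_index=np.zeros(n, int), year_index=np.zeros(n, int),
            site_ids=["s1"], years=[2000], species_ids=[f"sp{j}" for j in range(S)],
            has_year_re=False, year0=2000,
        )
        mcmc = MCMCSettings(n_chains=2, n_burn=150, n_thin=1, n_retain=200, seed=3)
        spreads = []
        for scale in (0.01, 100.0):
            f = fit(design, mcmc, Priors(mu0=np.zeros(2), fixed_v=scale * np.eye(2)),
                    include_site_re=False, include_year_re=False)
            spreads.append(f.beta_draws("x").mean(axis=0).std())
        assert spreads[0] < spreads[1]  # tight community prior contracts slopes


class TestPSRF:
    def test_identical_chains_give_exactly_one(self):
        chain = np.random.default_rng(0).normal(size=500)
        assert psrf(np.vstack([chain, chain])) == 1.0

    def test_divergent_means_blow_up(self):
        rng = np.random.default_rng(1)
        chains = np.vstack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert psrf(chains) > 2.0

    def test_zero_within_variance_unequal_means_is_inf(self):
        chains = np.vstack([np.full(20, 1.0), np.full(20, 2.0)])
        assert psrf(chains) == np.inf

    def test_requires_two_chains_and_ten_draws(self):
        with pytest.raises(ValueError):
            psrf(np.ones((1, 100)))
        with pytest.raises(ValueError):
            psrf(np.ones((2, 5)))


class TestFitMetrics:
    def test_perfect_separation(self):
        m = binary_metrics(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]))
        assert m["auc"] == 1.0 and m["tjur_r2"] == pytest.approx(0.7)

    def test_uninformative_predictions(self):
        m = binary_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.5))
        assert m["auc"] == 0.5
        assert m["tjur_r2"] == 0.0
        assert m["rmse"] == 0.5

    def test_printed_toy_auc_with_ties(self):
        m = binary_metrics(np.array([1, 1, 0, 0]), np.array([0.9, 0.6, 0.6, 0.1]))
        assert m["auc"] == pytest.approx(0.875)

    def test_single_class_species_reported_missing(self):
        m = binary_metrics(np.ones(5), np.linspace(0.1, 0.9, 5))
        assert np.isnan(m["auc"]) and np.isnan(m["tjur_r2"])

    def test_fit_metrics_frame_covers_all_species(self):
        design = intercept_only_design(7, 3)
        f = fit(design, MCMCSettings(n_chains=2, n_burn=50, n_thin=1, n_retain=60, seed=1),
                include_site_re=False, include_year_re=False)
        tab = fit_metrics(f)
        assert list(tab["species_id"]) == ["sp1"]
        assert 0 <= tab["rmse"].iloc[0] <= 1
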