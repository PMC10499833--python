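"""Propensity scores, Mahalanobis distances, greedy matching and balance."""

import numpy as np
import pandas as pd
import pytest

from paimpact import (
    MatchedDesign,
    balance_table,
    build_matched_design,
    estimate_propensity,
    greedy_match,
    mahalanobis_distance,
    select_method,
)
from paimpact.matching import matching_covariates, pooled_covariance


def _frame(protected, zone=None, **covs):
    n = len(protected)
    data = {
        "site_id": [f"S{i:03d}" for i in range(n)],
        "protected": protected,
        "vegetation_zone": zone if zone is not None else ["MB"] * n,
    }
    data.update({k: np.asarray(v, float) for k, v in covs.items()})
    return pd.DataFrame(data)


def brute_force_greedy(treated_scores, control_scores, caliper):
    """Independent sequential-greedy reference: process treated in
    descending score (index tie-break), nearest unused control within the
    caliper by absolute score distance (index tie-break)."""
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


class TestPropensity:
    def test_identical_covariates_give_treated_fraction(self):
        df = _frame([True] * 3 + [False] * 7, x=np.ones(10))
        scores = estimate_propensity(df, ["x"])
        assert np.allclose(scores, 0.3, atol=1e-6)

    def test_saturated_binary_covariate_recovers_stratum_proportions(self):
        # stratum x=0: 20 of 100 treated; stratum x=1: 50 of 100 treated
        x = np.r_[np.zeros(100), np.ones(100)]
        treated = np.r_[np.ones(20), np.zeros(80), np.ones(50), np.zeros(50)].astype(bool)
        df = _frame(list(treated), x=x)
        scores = estimate_propensity(df, ["x"]).to_numpy()
        assert np.allclose(scores[x == 0], 0.2, atol=1e-4)
        assert np.allclose(scores[x == 1], 0.5, atol=1e-4)

    def test_scores_invariant_to_affine_covariate_rescaling(self):
        rng = np.random.default_rng(0)
        df = _frame(list(rng.uniform(size=50) < 0.4), x=rng.normal(size=50), z=rng.normal(size=50))
        base = estimate_propensity(df, ["x", "z"])
        df2 = df.assign(x=df["x"] * 37.0 - 4.2)
        again = estimate_propensity(df2, ["x", "z"])
        assert np.allclose(base, again, atol=1e-6)

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        treated = rng.uniform(size=200) < 1 / (1 + np.exp(-(0.3 + 0.8 * x - 0.5 * z)))
        df = _frame(list(treated), x=x, z=z)
        ours = estimate_propensity(df, ["x", "z"]).to_numpy()
        X = sm.add_constant(np.column_stack([x, z]))
        ref = sm.GLM(treated.astype(float), X, family=sm.families.Binomial()).fit().fittedvalues
        assert np.allclose(ours, ref, atol=1e-6)

    def test_separation_falls_back_with_warning(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        df = _frame([False] * 10 + [True] * 10, x=x)
        with pytest.warns(RuntimeWarning, match="separation|ridge"):
            scores = estimate_propensity(df, ["x"])
        assert np.all((scores > 0) & (scores < 1))

    def test_all_treated_rejected(self):
        with pytest.raises(ValueError, match="treated"):
            estimate_propensity(_frame([True, True], x=[0.0, 1.0]), ["x"])


class TestMahalanobis:
    def test_identical_vectors_zero(self):
        S = np.eye(2)
        assert mahalanobis_distance([1.0, 2.0], [1.0, 2.0], S) == 0.0

    def test_identity_covariance_is_euclidean(self):
        d = mahalanobis_distance([3.0, 4.0], [0.0, 0.0], np.eye(2))
        assert d == pytest.approx(5.0)

    def test_hand_computed_example(self):
        d = mahalanobis_distance([1.0, 0.0], [0.0, 0.0], np.diag([4.0, 1.0]))
        assert d == pytest.approx(0.5)

    def test_singular_covariance_raises(self):
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_distance([1.0, 0.0], [0.0, 0.0], np.zeros((2, 2)))


class TestGreedyMatch:
    def test_single_pair_within_caliper(self):
        df = _frame([True, False], x=[0.0, 0.0])
        scores = pd.Series([0.52, 0.48], index=df["site_id"])
        design = greedy_match(df, scores, caliper_multiplier=2.0)
        assert design.pairs == [("S000", "S001")]

    def test_control_beyond_caliper_drops_treated(self):
        # the only control sits > 0.25 score-SDs away -> the treated is dropped
        df = _frame([True, False], x=[0.0, 0.0])
        scores = pd.Series([0.35, 0.65], index=df["site_id"])
        sd = scores.std(ddof=1)
        assert abs(0.65 - 0.35) > 0.25 * sd
        design = greedy_match(df, scores, caliper_multiplier=0.25)
        assert design.pairs == []
        # widening the caliper beyond the actual distance restores the pair
        assert greedy_match(df, scores, caliper_multiplier=2.0).pairs == [("S000", "S001")]

    def test_matches_brute_force_oracle_on_small_instances(self):
        rng = np.random.default_rng(17)
        for rep in range(50):
            nt = int(rng.integers(1, 7))
            nc = int(rng.integers(1, 7))
            scores_arr = np.round(rng.uniform(0.05, 0.95, nt + nc), 3)
            df = _frame([True] * nt + [False] * nc, x=np.zeros(nt + nc))
            scores = pd.Series(scores_arr, index=df["site_id"])
            design = greedy_match(df, scores, caliper_multiplier=0.25)
            cal = 0.25 * scores.std(ddof=1)
            expect = brute_force_greedy(
                {s: scores[s] for s in df.loc[df.protected, "site_id"]},
                {s: scores[s] for s in df.loc[~df.protected, "site_id"]},
                cal,
            )
            assert design.pairs == expect, f"rep {rep}"
            controls = [c for _, c in design.pairs]
            assert len(controls) == len(set(controls))
            assert all(abs(scores[t] - scores[c]) <= cal for t, c in design.pairs)

    def test_zone_strata_are_exact(self, small_site_frame):
        covs = matching_covariates("birds")
        scores = estimate_propensity(small_site_frame, covs)
        design = greedy_match(small_site_frame, scores, 1.0)
        zone = small_site_frame.set_index("site_id")["vegetation_zone"]
        assert all(zone[t] == zone[c] for t, c in design.pairs)

    def test_empty_stratum_warns_and_drops(self):
        df = _frame([True, True, False], zone=["NB", "NB", "MB"], x=[0.0, 0.1, 0.2])
        scores = pd.Series([0.5, 0.6, 0.4], index=df["site_id"])
        with pytest.warns(RuntimeWarning, match="no controls"):
            design = greedy_match(df, scores, 1.0)
        assert all(zone == "MB" for zone in [])  # NB treated dropped
        assert design.pairs == []


class TestBalance:
    def test_identical_groups_zero_smd(self):
        df = _frame([True, False], x=[1.0, 1.0])
        design = MatchedDesign([("S000", "S001")], "propensity", 0.25)
        tab = balance_table(df, design, ["x"])
        assert tab["smd_before"].iloc[0] == 0.0
        assert tab["smd_after"].iloc[0] == 0.0

    def test_unit_mean_difference_gives_smd_one(self):
        rng = np.random.default_rng(1)
        n = 4000
        x = np.r_[rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)]
        df = _frame([True] * n + [False] * n, x=x)
        design = MatchedDesign([("S000", f"S{n:03d}")], "propensity", 0.25)
        tab = balance_table(df, design, ["x"])
        assert tab["smd_before"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_exact_matching_zeroes_after_smd(self):
        df = _frame([True, True, False, False], x=[3.0, 5.0, 3.0, 5.0])
        design = MatchedDesign([("S000", "S002"), ("S001", "S003")], "propensity", 0.25)
        tab = balance_table(df, design, ["x"])
        assert tab["smd_after"].iloc[0] == 0.0


class TestSelectMethod:
    def _design(self, method, smd, n):
        pairs = [(f"T{i}", f"C{i}") for i in range(n)]
        bal = pd.DataFrame({"covariate": ["x"], "smd_before": [1.0], "smd_after": [smd]})
        return MatchedDesign(pairs, method, 0.25, balance=bal)

    def test_smaller_mean_smd_wins(self):
        assert select_method(
            [self._design("propensity", 0.12, 10), self._design("mahalanobis", 0.05, 10)]
        ).method == "mahalanobis"

    def test_tie_breaks_to_larger_n(self):
        assert select_method(
            [self._design("mahalanobis", 0.05, 50), self._design("propensity", 0.05, 40)]
        ).n_matched == 50

    def test_final_tie_breaks_to_propensity(self):
        assert select_method(
            [self._design("mahalanobis", 0.05, 10), self._design("propensity", 0.05, 10)]
        ).method == "propensity"


class TestEndToEnd:
    def test_design_invariants_on_synthetic_landscape(self, small_site_frame):
        design = build_matched_design(small_site_frame, "birds")
        assert design.n_matched >= 1
        assert len(set(design.site_ids)) == 2 * design.n_matched
        assert not design.balance.empty

    def test_no_replacement_enforced_by_container(self):
        with pytest.raises(ValueError, match="more than one pair"):
            MatchedDesign([("T1", "C1"), ("T2", "C1")], "propensity", 0.25)

    def test_pooled_covariance_positive_definite(self):
        rng = np.random.default_rng(0)
        S = pooled_covariance(rng.normal(size=(30, 4)), rng.normal(size=(40, 4)))
        assert np.all(np.linalg.eigvalsh(S) > 0)
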