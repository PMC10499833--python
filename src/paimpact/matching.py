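"""Matched protected/unprotected study design.

Each protected site is paired with its most similar unprotected site by
one-to-one greedy nearest-neighbour matching without replacement, inside
exact vegetation-zone strata, under a caliper of 0.25 SD of the
propensity scores.  Two distance metrics are supported — the propensity
score (logistic model of protection on the matching covariates) and the
Mahalanobis distance — and the better-balancing method is selected per
dataset by mean absolute standardized mean difference (SMD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

DEFAULT_CALIPER = 0.25


@dataclass
class MatchedDesign:
    """Pairs of (treated, control) site ids plus balance diagnostics."""

    pairs: list[tuple[str, str]]
    method: str  # propensity | mahalanobis
    caliper_multiplier: float
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)  # covariate, smd_before, smd_after
    n_treated_total: int = 0

    def __post_init__(self) -> None:
        used = [c for _, c in self.pairs]
        if len(used) != len(set(used)):
            raise ValueError("a control site appears in more than one pair")
        treated = [t for t, _ in self.pairs]
        if len(treated) != len(set(treated)):
            raise ValueError("a treated site appears in more than one pair")

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def site_ids(self) -> list[str]:
        return [s for pair in self.pairs for s in pair]

    @property
    def mean_after_smd(self) -> float:
        return float(self.balance["smd_after"].abs().mean()) if len(self.balance) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])


def matching_covariates(taxon_group: str) -> list[str]:
    """Covariate columns entering the distance metric for a taxon.

    All taxa match on the 8 land-cover proportions and mean survey year;
    birds and mammals add survey effort; phytoplankton adds the 4 lake
    covariates.  Vegetation zone is an exact stratum, never a distance
    covariate.
    """
    from .synthdata import COVARIATE_NAMES, LAKE_COVARIATE_NAMES

    cols = list(COVARIATE_NAMES) + ["mean_survey_year"]
    if taxon_group in ("birds", "mammals"):
        cols.append("effort")
    elif taxon_group == "phytoplankton":
        cols += LAKE_COVARIATE_NAMES
    return cols


def _logistic_irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS logistic fit; returns (coefficients, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * W) @ X + ridge * np.eye(p)
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        eta = np.clip(X @ beta, -30, 30)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta)))) - 0.5 * ridge * beta @ beta
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            return beta, True
        ll_old = ll
    return beta, False


def estimate_propensity(
    sites: pd.DataFrame, covariate_names: Sequence[str]
) -> pd.Series:
    """Propensity of protection from a logistic model on the covariates.

    Fitted by iteratively reweighted least squares; under (quasi-)perfect
    separation or non-convergence a ridge-stabilized refit is used and a
    warning issued.  Returns fitted probabilities indexed by site_id.
    """
    treated = sites["protected"].astype(bool).to_numpy()
    if treated.all() or not treated.any():
        raise ValueError("need at least one treated and one control site")
    Z = sites[list(covariate_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite matching covariates")
    # standardize for numerical stability; fitted probabilities are invariant.
    # zero-variance covariates carry no information and are dropped.
    sd = Z.std(axis=0, ddof=0)
    Z = (Z[:, sd > 0] - Z[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    X = np.column_stack([np.ones(len(treated)), Z])
    beta, converged = _logistic_irls(X, treated.astype(float))
    eta = X @ beta
    if not converged or np.abs(eta).max() > 15:
        warnings.warn(
            "propensity model separation or non-convergence; using ridge-stabilized fit",
            RuntimeWarning,
        )
        beta, _ = _logistic_irls(X, treated.astype(float), ridge=1e-3)
        eta = X @ beta
    return pd.Series(expit(eta), index=sites["site_id"].to_numpy(), name="propensity")


def pooled_covariance(
    treated: np.ndarray, controls: np.ndarray, ridge: float = 1e-8
) -> np.ndarray:
    """Pooled within-group covariance used by the Mahalanobis metric."""
    parts = [g for g in (treated, controls) if len(g) >= 2]
    if not parts:
        raise ValueError("need at least two sites in one group")
    covs = [np.cov(g, rowvar=False, ddof=1) for g in parts]
    S = np.mean(covs, axis=0)
    S = np.atleast_2d(S) + ridge * np.eye(S.shape[0] if S.ndim else 1)
    return S


def mahalanobis_distance(x_t: np.ndarray, x_c: np.ndarray, S: np.ndarray) -> float:
    """d = sqrt((x_t - x_c)' S^-1 (x_t - x_c)); S must be positive definite."""
    diff = np.asarray(x_t, dtype=float) - np.asarray(x_c, dtype=float)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance singular even after ridge") from exc
    v = np.linalg.solve(L, diff)
    return float(np.sqrt(v @ v))


def greedy_match(
    sites: pd.DataFrame,
    scores: pd.Series,
    caliper_multiplier: float = DEFAULT_CALIPER,
    method: str = "propensity",
    covariate_names: Optional[Sequence[str]] = None,
) -> MatchedDesign:
    """One-to-one greedy nearest-neighbour matching without replacement.

    Within each vegetation-zone stratum, treated sites are processed in
    descending propensity score (site_id tie-break); each receives the
    closest unused control whose score distance is within
    ``caliper * SD(scores)``, or is dropped.  With ``method='mahalanobis'``
    the nearest control is chosen by Mahalanobis distance on the matching
    covariates, while the caliper still constrains the score distance.
    """
    if method not in ("propensity", "mahalanobis"):
        raise ValueError(f"unknown matching method {method!r}")
    sites = sites.reset_index(drop=True)
    score_sd = float(scores.std(ddof=1))
    caliper = caliper_multiplier * score_sd

    pairs: list[tuple[str, str]] = []
    for zone, stratum in sites.groupby("vegetation_zone", sort=True):
        tr = stratum[stratum["protected"].astype(bool)]
        co = stratum[~stratum["protected"].astype(bool)]
        if len(tr) and not len(co):
            warnings.warn(f"stratum {zone}: no controls; {len(tr)} treated dropped", RuntimeWarning)
            continue
        if not len(tr):
            continue
        order = sorted(tr["site_id"], key=lambda s: (-scores[s], s))
        available = set(co["site_id"])
        if method == "mahalanobis":
            cols = list(covariate_names or [])
            if not cols:
                raise ValueError("mahalanobis matching requires covariate_names")
            X = stratum.set_index("site_id")[cols].astype(float)
            S = pooled_covariance(
                X.loc[tr["site_id"]].to_numpy(), X.loc[co["site_id"]].to_numpy()
            )
        for t in order:
            best, best_d = None, np.inf
            for c in sorted(available):
                if abs(scores[t] - scores[c]) > caliper:
                    continue
                d = (
                    abs(scores[t] - scores[c])
                    if method == "propensity"
                    else mahalanobis_distance(X.loc[t].to_numpy(), X.loc[c].to_numpy(), S)
                )
                if d < best_d:
                    best, best_d = c, d
            if best is not None:
                pairs.append((t, best))
                available.remove(best)
    return MatchedDesign(
        pairs=pairs,
        method=method,
        caliper_multiplier=caliper_multiplier,
        n_treated_total=int(sites["protected"].astype(bool).sum()),
    )


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = a.mean(), b.mean()
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0) if min(len(a), len(b)) > 1 else 0.0
    if pooled == 0:
        return 0.0 if np.isclose(ma, mb) else np.inf
    return float(abs(ma - mb) / pooled)


def balance_table(
    sites: pd.DataFrame, design: MatchedDesign, covariate_names: Sequence[str]
) -> pd.DataFrame:
    """Absolute SMD per covariate, before (all treated vs all controls)
    and after matching (matched treated vs matched controls)."""
    if not design.pairs:
        raise ValueError("empty design")
    df = sites.set_index("site_id")
    tr_all = df[df["protected"].astype(bool)]
    co_all = df[~df["protected"].astype(bool)]
    tr_m = df.loc[[t for t, _ in design.pairs]]
    co_m = df.loc[[c for _, c in design.pairs]]
    rows = []
    for cov in covariate_names:
        rows.append(
            {
                "covariate": cov,
                "smd_before": _smd(tr_all[cov].to_numpy(float), co_all[cov].to_numpy(float)),
                "smd_after": _smd(tr_m[cov].to_numpy(float), co_m[cov].to_numpy(float)),
            }
        )
    return pd.DataFrame(rows)


def select_method(designs: Sequence[MatchedDesign]) -> MatchedDesign:
    """Pick the design with the smaller mean absolute after-SMD; ties break
    toward larger n_matched, then toward the propensity method."""

    def key(d: MatchedDesign):
        smd = d.mean_after_smd
        return (np.inf if np.isnan(smd) else smd, -d.n_matched, d.method != "propensity")

    return min(designs, key=key)


def build_matched_design(
    sites: pd.DataFrame,
    taxon_group: str,
    method: str = "auto",
    caliper_multiplier: float = DEFAULT_CALIPER,
) -> MatchedDesign:
    """Run matching end to end on a site table with a ``protected`` column."""
    covs = matching_covariates(taxon_group)
    scores = estimate_propensity(sites, covs)
    candidates = []
    methods = ("propensity", "mahalanobis") if method == "auto" else (method,)
    for m in methods:
        design = greedy_match(sites, scores, caliper_multiplier, m, covariate_names=covs)
        if design.pairs:
            design.balance = balance_table(sites, design, covs)
        candidates.append(design)
    return select_method(candidates) if len(candidates) > 1 else candidates[0]
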