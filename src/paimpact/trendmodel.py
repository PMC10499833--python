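"""Hierarchical Bayesian multispecies probit occupancy-trend model.

The model for species *j* at sampling unit *u* (a surveyed site-year) is

    P(y_uj = 1) = Phi( x_u' beta_j + a_site(u) + b_year(u) )

with fixed-effect columns intercept, protection status, rescaled year
(1 = earliest survey year), protection x year — the inferential target —
two vegetation-zone indicators, and standardized log effort (or log lake
size).  Species coefficient vectors are pooled through a community-level
multivariate normal, beta_j ~ N(mu, V), and exchangeable site and year
random intercepts absorb spatial and temporal autocorrelation.

Inference is by Gibbs sampling with latent-utility data augmentation:
truncated-normal draws of the latent utilities, conjugate multivariate
normal updates of each species' coefficients, a Normal-Inverse-Wishart
update of (mu, V), conjugate normal updates of the random intercepts and
inverse-gamma updates of their variances.  Convergence is assessed with
the Gelman-Rubin potential scale reduction factor and fit with AUC,
Tjur R-squared and RMSE on posterior-mean occurrence probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import ndtr, ndtri
from scipy.stats import wishart
from sklearn.metrics import roc_auc_score

from .config import MCMCSettings

logger = logging.getLogger(__name__)

MIN_RECORDS = 10  # species with fewer presences are excluded


def filter_species(records: pd.DataFrame, min_records: int = MIN_RECORDS) -> pd.DataFrame:
    """Drop species with fewer than ``min_records`` presences overall."""
    counts = records.groupby("species_id")["occ"].sum()
    keep = counts[counts >= min_records].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("filter_species: removed %d species with <%d records: %s",
                    len(dropped), min_records, ", ".join(dropped[:10]))
    out = records[records["species_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            "no species left after the <%d-record filter; simulate more data" % min_records
        )
    return out


@dataclass
class TrendDesign:
    """Response matrix and design matrix over (site, year) sampling units."""

    Y: np.ndarray  # (n_units, n_species) 0/1
    X: np.ndarray  # (n_units, p)
    colnames: list[str]
    site_index: np.ndarray  # (n_units,) -> site_ids
    year_index: np.ndarray  # (n_units,) -> years
    site_ids: list[str]
    years: list[int]
    species_ids: list[str]
    has_year_re: bool
    year0: int

    def __post_init__(self) -> None:
        if np.isnan(self.Y).any() or not np.all(np.isfinite(self.X)):
            raise ValueError("design contains missing values")
        if "year_rescaled" in self.colnames:
            t = self.X[:, self.colnames.index("year_rescaled")]
            if t.min() < 1:
                raise ValueError("year_rescaled must be >= 1")

    @property
    def n_units(self) -> int:
        return self.Y.shape[0]

    @property
    def n_species(self) -> int:
        return self.Y.shape[1]


def build_design(
    records: pd.DataFrame,
    protection: pd.DataFrame,
    zones: pd.Series,
    effort: Optional[pd.Series] = None,
    subset_window: Optional[str] = None,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    include_year_re: bool = True,
) -> TrendDesign:
    """Assemble the trend-model design from occurrence records.

    ``zones`` maps site_id -> vegetation zone; ``effort`` (optional) maps
    site_id -> a positive effort/lake-size value that enters as
    standardized log effort.  ``subset_window='post_establishment'`` keeps,
    for each protected site, only years from the attributed PA's
    establishment year on; matched controls (via ``pairs``) are trimmed to
    the same window as their partner.
    """
    records = records.copy()
    prot_tab = protection.set_index("site_id")
    missing = set(records["site_id"]) - set(prot_tab.index)
    if missing:
        raise ValueError(f"sites missing from protection table: {sorted(missing)[:5]}")
    missing_zone = set(records["site_id"]) - set(zones.index)
    if missing_zone:
        raise ValueError(f"sites lacking zone labels: {sorted(missing_zone)[:5]}")

    if subset_window == "post_establishment":
        start: dict[str, int] = {}
        for sid in records["site_id"].unique():
            if bool(prot_tab.loc[sid, "protected"]):
                est = int(prot_tab.loc[sid, "year_established"])
                if est > 0:
                    start[sid] = est
        if pairs:
            for t, c in pairs:
                if t in start:
                    start[c] = start[t]
        if start:
            keep = records.apply(
                lambda r: r["year"] >= start.get(r["site_id"], -(10**9)), axis=1
            )
            records = records[keep].reset_index(drop=True)
        if records.empty:
            raise ValueError("post-establishment window removed all records")
    elif subset_window is not None:
        raise ValueError(f"unknown subset_window {subset_window!r}")

    species = sorted(records["species_id"].unique())
    wide = records.pivot_table(
        index=["site_id", "year"], columns="species_id", values="occ", aggfunc="max"
    )[species]
    if wide.isna().any().any():
        raise ValueError("unbalanced species records: some site-years miss species rows")
    units = wide.index.to_frame(index=False)
    site_ids = sorted(units["site_id"].unique())
    years = sorted(int(y) for y in units["year"].unique())
    year0 = years[0]

    site_pos = {s: i for i, s in enumerate(site_ids)}
    year_pos = {y: i for i, y in enumerate(years)}
    site_index = units["site_id"].map(site_pos).to_numpy()
    year_index = units["year"].map(year_pos).to_numpy()

    protected = units["site_id"].map(prot_tab["protected"].astype(bool)).to_numpy(float)
    t = (units["year"].to_numpy(int) - year0 + 1).astype(float)
    zone = units["site_id"].map(zones)
    cols = {
        "intercept": np.ones(len(units)),
        "protected": protected,
        "year_rescaled": t,
        "prot_x_year": protected * t,
        "zone_MB": (zone == "MB").to_numpy(float),
        "zone_NB": (zone == "NB").to_numpy(float),
    }
    if effort is not None:
        le = np.log(units["site_id"].map(effort).to_numpy(float))
        sd = le.std()
        cols["log_effort"] = (le - le.mean()) / sd if sd > 0 else le * 0.0
    X = np.column_stack(list(cols.values()))
    return TrendDesign(
        Y=wide.to_numpy(float),
        X=X,
        colnames=list(cols.keys()),
        site_index=site_index,
        year_index=year_index,
        site_ids=site_ids,
        years=years,
        species_ids=species,
        has_year_re=include_year_re,
        year0=year0,
    )


@dataclass
class Priors:
    """Weakly informative conjugate priors for the hierarchical model.

    The community mean and covariance get a Normal-Inverse-Wishart prior:
    mu | V ~ N(mu0, V / kappa0) with small kappa0 (diffuse mean),
    V ~ IW(p + 2, I); random-effect variances get InverseGamma(1, 1).
    ``fixed_v`` switches off the community update and fixes (mu, V) =
    (mu0, fixed_v) — the conjugate-limit configuration used by oracle
    tests on a single species.
    """

    kappa0: float = 0.04
    mu0: Optional[np.ndarray] = None
    niw_df: Optional[float] = None
    niw_scale: Optional[np.ndarray] = None
    ig_shape: float = 1.0
    ig_rate: float = 1.0
    fixed_v: Optional[np.ndarray] = None


@dataclass
class TrendModelFit:
    """Posterior samples (chains x draws) and diagnostics."""

    beta: np.ndarray  # (chains, draws, p, S)
    mu: np.ndarray  # (chains, draws, p)
    V: np.ndarray  # (chains, draws, p, p)
    site_re: np.ndarray  # (chains, draws, n_sites)
    year_re: np.ndarray  # (chains, draws, n_years) (zeros if absent)
    sigma2_site: np.ndarray  # (chains, draws)
    sigma2_year: np.ndarray
    pred_mean: np.ndarray  # (n_units, S) posterior-mean occurrence probabilities
    colnames: list[str]
    species_ids: list[str]
    design: TrendDesign = field(repr=False)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    def beta_draws(self, column: str) -> np.ndarray:
        """Pooled posterior draws of one coefficient, shape (draws_total, S)."""
        k = self.colnames.index(column)
        return self.beta[:, :, k, :].reshape(-1, len(self.species_ids))

    def psrf_table(self) -> pd.DataFrame:
        """Gelman-Rubin PSRF for every species-level coefficient."""
        rows = []
        for k, col in enumerate(self.colnames):
            for j, sp in enumerate(self.species_ids):
                rows.append(
                    {"species_id": sp, "coefficient": col, "psrf": psrf(self.beta[:, :, k, j])}
                )
        return pd.DataFrame(rows)

    def max_psrf(self) -> float:
        tab = self.psrf_table()
        return float(tab["psrf"].max())

    def converged(self, limit: float = 1.1) -> bool:
        return self.max_psrf() < limit


def _draw_truncated(rng: np.random.Generator, eta: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """z ~ N(eta, 1) truncated to z > 0 (positive) or z <= 0, via inverse CDF."""
    u = rng.uniform(size=eta.shape)
    lo = ndtr(-eta)  # P(z <= 0)
    arg = np.where(positive, lo + u * (1.0 - lo), u * lo)
    z = eta + ndtri(np.clip(arg, 1e-15, 1.0 - 1e-15))
    # numerical safeguard deep in the tails: keep the sign consistent with y
    return np.where(positive, np.maximum(z, 1e-10), np.minimum(z, -1e-10))


def fit(
    design: TrendDesign,
    mcmc: Optional[MCMCSettings] = None,
    priors: Optional[Priors] = None,
    include_site_re: bool = True,
    include_year_re: Optional[bool] = None,
) -> TrendModelFit:
    """Run the Gibbs sampler; chains differ by seed and overdispersed inits."""
    mcmc = mcmc or MCMCSettings()
    priors = priors or Priors()
    if mcmc.n_chains < 1:
        raise ValueError("need at least one chain")
    if include_year_re is None:
        include_year_re = design.has_year_re

    Y, X = design.Y, design.X
    n, S = Y.shape
    p = X.shape[1]
    positive = Y > 0.5
    XtX = X.T @ X
    n_sites = len(design.site_ids)
    n_years = len(design.years)
    site_counts = np.bincount(design.site_index, minlength=n_sites).astype(float) * S
    year_counts = np.bincount(design.year_index, minlength=n_years).astype(float) * S

    mu0 = np.zeros(p) if priors.mu0 is None else np.asarray(priors.mu0, float)
    niw_df = float(priors.niw_df if priors.niw_df is not None else p + 2)
    S0 = np.eye(p) if priors.niw_scale is None else np.asarray(priors.niw_scale, float)
    fixed_community = priors.fixed_v is not None

    n_iter = mcmc.n_burn + mcmc.n_thin * mcmc.n_retain
    shape = (mcmc.n_chains, mcmc.n_retain)
    out = TrendModelFit(
        beta=np.empty(shape + (p, S)),
        mu=np.empty(shape + (p,)),
        V=np.empty(shape + (p, p)),
        site_re=np.zeros(shape + (n_sites,)),
        year_re=np.zeros(shape + (n_years,)),
        sigma2_site=np.ones(shape),
        sigma2_year=np.ones(shape),
        pred_mean=np.zeros((n, S)),
        colnames=list(design.colnames),
        species_ids=list(design.species_ids),
        design=design,
    )
    n_pred = 0

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(int(mcmc.seed), spawn_key=(91, chain))
        )
        # overdispersed initialization per chain
        B = rng.normal(0.0, 0.25 * (1 + chain), size=(p, S))
        mu = mu0.copy()
        V = np.asarray(priors.fixed_v, float).copy() if fixed_community else np.eye(p)
        a = np.zeros(n_sites)
        b = np.zeros(n_years)
        s2a, s2b = 0.25, 0.25
        kept = 0

        for it in range(n_iter):
            re_term = a[design.site_index] if include_site_re else 0.0
            if include_year_re:
                re_term = re_term + b[design.year_index]
            eta = X @ B
            if isinstance(re_term, np.ndarray):
                eta += re_term[:, None]
            if not np.all(np.isfinite(eta)):
                bad = np.argwhere(~np.isfinite(eta))[0]
                raise FloatingPointError(
                    f"non-finite linear predictor (chain {chain}, iter {it}, "
                    f"unit {bad[0]}, species {design.species_ids[bad[1]]})"
                )
            Z = _draw_truncated(rng, eta, positive)

            # species coefficients (shared posterior precision across species)
            Vinv = sla.inv(V)
            prec = XtX + Vinv
            L = sla.cholesky(prec, lower=True)
            R = Z - re_term[:, None] if isinstance(re_term, np.ndarray) else Z
            rhs = X.T @ R + (Vinv @ mu)[:, None]
            mean = sla.cho_solve((L, True), rhs)
            B = mean + sla.solve_triangular(
                L.T, rng.standard_normal((p, S)), lower=False
            )

            # community-level Normal-Inverse-Wishart update
            if not fixed_community:
                Bbar = B.mean(axis=1)
                dev = B - Bbar[:, None]
                scatter = dev @ dev.T
                kap_n = priors.kappa0 + S
                m_n = (priors.kappa0 * mu0 + S * Bbar) / kap_n
                d0 = (Bbar - mu0)[:, None]
                S_n = S0 + scatter + (priors.kappa0 * S / kap_n) * (d0 @ d0.T)
                W = wishart.rvs(df=niw_df + S, scale=sla.inv(S_n), random_state=rng)
                V = sla.inv(np.atleast_2d(W))
                mu = m_n + np.linalg.cholesky(V / kap_n) @ rng.standard_normal(p)

            # site / year random intercepts and their variances
            if include_site_re:
                E = Z - X @ B
                if include_year_re:
                    E = E - b[design.year_index][:, None]
                sums = np.bincount(design.site_index, weights=E.sum(axis=1), minlength=n_sites)
                prec_a = site_counts + 1.0 / s2a
                a = sums / prec_a + rng.standard_normal(n_sites) / np.sqrt(prec_a)
                s2a = (priors.ig_rate + 0.5 * a @ a) / rng.gamma(
                    priors.ig_shape + 0.5 * n_sites
                )
            if include_year_re:
                E = Z - X @ B
                if include_site_re:
                    E = E - a[design.site_index][:, None]
                sums = np.bincount(design.year_index, weights=E.sum(axis=1), minlength=n_years)
                prec_b = year_counts + 1.0 / s2b
                b = sums / prec_b + rng.standard_normal(n_years) / np.sqrt(prec_b)
                s2b = (priors.ig_rate + 0.5 * b @ b) / rng.gamma(
                    priors.ig_shape + 0.5 * n_years
                )

            if it >= mcmc.n_burn and (it - mcmc.n_burn) % mcmc.n_thin == 0:
                out.beta[chain, kept] = B
                out.mu[chain, kept] = mu
                out.V[chain, kept] = V
                if include_site_re:
                    out.site_re[chain, kept] = a
                    out.sigma2_site[chain, kept] = s2a
                if include_year_re:
                    out.year_re[chain, kept] = b
                    out.sigma2_year[chain, kept] = s2b
                eta = X @ B
                if include_site_re:
                    eta += a[design.site_index][:, None]
                if include_year_re:
                    eta += b[design.year_index][:, None]
                out.pred_mean += ndtr(eta)
                n_pred += 1
                kept += 1

    out.pred_mean /= max(n_pred, 1)
    return out


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n): m >= 2 chains of n >= 10 draws each.
    Values below 1 are floored at 1.0 (a between-chain variance smaller
    than the within-chain variance carries no convergence information).
    Zero within-chain variance with unequal chain means yields +inf.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    means = chains.mean(axis=1)
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0 if np.allclose(means, means[0]) else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(max(np.sqrt(var_plus / W), 1.0))


def binary_metrics(y: np.ndarray, phat: np.ndarray) -> dict[str, float]:
    """AUC (ties count 1/2), Tjur R-squared and RMSE for one species.

    Species observed in a single class get missing values, since neither
    discrimination statistic is defined there.
    """
    y = np.asarray(y, float)
    phat = np.asarray(phat, float)
    if y.min() == y.max():
        return {"auc": np.nan, "tjur_r2": np.nan, "rmse": np.nan}
    return {
        "auc": float(roc_auc_score(y, phat)),
        "tjur_r2": float(phat[y == 1].mean() - phat[y == 0].mean()),
        "rmse": float(np.sqrt(np.mean((y - phat) ** 2))),
    }


def fit_metrics(fit: TrendModelFit, design: Optional[TrendDesign] = None) -> pd.DataFrame:
    """Per-species AUC, Tjur R-squared and RMSE from posterior-mean
    occurrence probabilities."""
    design = design or fit.design
    rows = []
    for j, sp in enumerate(fit.species_ids):
        rows.append(
            {"species_id": sp, **binary_metrics(design.Y[:, j], fit.pred_mean[:, j])}
        )
    return pd.DataFrame(rows)
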