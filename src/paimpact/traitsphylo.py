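"""Trait regressions and phylogenetic signal in protection effects.

Per-taxon ordinary least squares relates the species-level protection
effect (posterior mean of the protection x year interaction) to log body
size, the species temperature index and threat status — predictors being
available per taxon (no threat status for plants; neither threat status
nor STI for phytoplankton).  Phylogenetic signal in the effects is
measured with Blomberg's K (significance by tip-label permutation) and
the maximum-likelihood estimate of Pagel's lambda under a Brownian-motion
model on the phylogenetic covariance matrix.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import shapiro

from .synthdata import tree_vcv

#: Predictors usable per taxonomic group.
TAXON_PREDICTORS = {
    "birds": ("log_body_size", "sti", "threat"),
    "mammals": ("log_body_size", "sti", "threat"),
    "plants": ("log_body_size", "sti"),
    "phytoplankton": ("log_body_size",),
}


def trait_regression(
    effects: pd.Series,
    traits: pd.DataFrame,
    taxon: str,
    predictors: Optional[Sequence[str]] = None,
) -> dict:
    """OLS of the protection effect on species traits for one taxon.

    ``effects`` is indexed by species_id.  Returns a dict with the
    coefficient table (estimate, SE, t, p), the pairwise predictor
    correlation matrix and a residual-normality (Shapiro-Wilk) summary.
    """
    predictors = list(predictors if predictors is not None else TAXON_PREDICTORS[taxon])
    df = traits.set_index("species_id").copy()
    df["log_body_size"] = np.log(df["body_size"].astype(float))
    if "threat" in predictors:
        df["threat"] = (df["threat"] == "threatened").astype(float)
    common = effects.index.intersection(df.index)
    df = df.loc[common]
    y = effects.loc[common].astype(float)
    Xd = df[predictors].astype(float)
    complete = Xd.notna().all(axis=1) & y.notna()
    Xd, y = Xd[complete], y[complete]
    if len(y) < len(predictors) + 2:
        raise ValueError("too few species with complete traits for regression")
    X = sm.add_constant(Xd)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = Xd.corr()
        bad = [c for c in predictors if (corr[c].drop(c).abs() > 0.999).any()]
        raise ValueError(f"rank-deficient trait design; collinear columns: {bad or predictors}")
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    table = pd.DataFrame(
        {
            "predictor": ["intercept"] + predictors,
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    resid = res.resid
    norm_p = float(shapiro(resid)[1]) if 3 <= len(resid) <= 5000 else np.nan
    return {
        "taxon": taxon,
        "coefficients": table,
        "n": int(len(y)),
        "r2": float(res.rsquared),
        "predictor_correlations": Xd.corr(),
        "residual_normality_p": norm_p,
    }


def _align_tree_trait(newick: str, trait: pd.Series):
    """Phylogenetic covariance restricted to tips with trait values.

    Tips absent from the trait vector (e.g. species dropped by the
    <10-record filter) are pruned; a trait value without a matching tip is
    an error, as is a constant trait.
    """
    V, labels = tree_vcv(newick)
    unmatched = set(trait.index) - set(labels)
    if unmatched:
        raise ValueError(f"trait values without matching tips: {sorted(unmatched)[:5]}")
    keep = [i for i, l in enumerate(labels) if np.isfinite(trait.get(l, np.nan))]
    if len(keep) < 3:
        raise ValueError("need trait values for at least 3 tips")
    labels = [labels[i] for i in keep]
    x = trait.reindex(labels).to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance trait")
    return V[np.ix_(keep, keep)], x, labels


def _gls_mean(V_inv: np.ndarray, x: np.ndarray) -> float:
    one = np.ones(len(x))
    return float(one @ V_inv @ x / (one @ V_inv @ one))


def blomberg_k(
    newick: str,
    trait: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Blomberg's K with a tip-label permutation p-value.

    K compares the observed ratio of trait variance to phylogenetically
    corrected variance against its Brownian-motion expectation on the same
    tree; K ~ 1 under BM, K -> 0 when trait values are independent of the
    phylogeny.  The p-value is the fraction of ``n_permutations`` random
    tip relabellings (plus the observed one) with K at least as large.
    """
    V, x, labels = _align_tree_trait(newick, trait)
    n = len(x)
    V_inv = np.linalg.inv(V)
    one = np.ones(n)
    denom_expected = (np.trace(V) - n / (one @ V_inv @ one)) / (n - 1)

    def k_stat(vals: np.ndarray) -> float:
        a = _gls_mean(V_inv, vals)
        dev = vals - a
        mse0 = dev @ dev / (n - 1)
        mse = dev @ V_inv @ dev / (n - 1)
        return float((mse0 / mse) / denom_expected)

    k_obs = k_stat(x)
    rng = np.random.default_rng(seed)
    hits = 1  # the observed arrangement counts
    for _ in range(n_permutations):
        if k_stat(rng.permutation(x)) >= k_obs:
            hits += 1
    return k_obs, hits / (n_permutations + 1)


def _lambda_loglik(lam: float, x: np.ndarray, V: np.ndarray) -> float:
    n = len(x)
    Vl = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    sign, logdet = np.linalg.slogdet(Vl)
    if sign <= 0:
        return -np.inf
    Vl_inv = np.linalg.inv(Vl)
    a = _gls_mean(Vl_inv, x)
    dev = x - a
    q = dev @ Vl_inv @ dev
    if q <= 0:
        return -np.inf
    sigma2 = q / n
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda(newick: str, trait: pd.Series) -> tuple[float, float]:
    """Maximum-likelihood Pagel's lambda in [0, 1] with its log-likelihood.

    lambda scales the off-diagonal (shared-history) entries of the
    phylogenetic covariance: 1 = pure Brownian motion, 0 = star phylogeny
    (no signal).  Optimized by bounded 1-D search (tolerance 1e-6); a
    boundary optimum is reported with a warning, never hidden.
    """
    V, x, _ = _align_tree_trait(newick, trait)
    res = minimize_scalar(
        lambda lam: -_lambda_loglik(lam, x, V),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat, ll_hat = float(res.x), float(-res.fun)
    # the bounded optimizer never quite reaches the ends; check them explicitly
    for edge in (0.0, 1.0):
        ll_edge = _lambda_loglik(edge, x, V)
        if ll_edge > ll_hat:
            lam_hat, ll_hat = edge, ll_edge
    if lam_hat in (0.0, 1.0) or min(lam_hat, 1.0 - lam_hat) < 1e-4:
        warnings.warn(f"lambda optimum at boundary ({lam_hat:.4f})", RuntimeWarning)
    return lam_hat, ll_hat


def signal_table(
    newick: str, effects: pd.Series, taxon: str, seed: int = 0, n_permutations: int = 999
) -> pd.DataFrame:
    """Blomberg's K and Pagel's lambda for one taxon's protection effects."""
    k, p = blomberg_k(newick, effects, n_permutations=n_permutations, seed=seed)
    lam, ll = pagel_lambda(newick, effects)
    return pd.DataFrame(
        [
            {"taxon": taxon, "statistic": "blomberg_k", "value": k, "p_or_loglik": p},
            {"taxon": taxon, "statistic": "pagel_lambda", "value": lam, "p_or_loglik": ll},
        ]
    )
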