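"""Posterior classification of species responses to protection.

A species responds to protection when the posterior probability that its
protection x year interaction is positive (or negative) reaches 90%;
responses below that support are classified *none*.  Responding species
are further sorted into the six processes by which a protected area can
reshape an occurrence trend, from the signs of the posterior-mean slopes
outside (beta_year) and inside (beta_year + beta_int) protected areas:
alleviated or accelerated declines, alleviated or accelerated increases,
and trend inversions in either direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matching import MatchedDesign

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.90

RESPONSE_CLASSES = ("positive", "negative", "none")
PROCESS_CATEGORIES = (
    "alleviated_decline",
    "accelerated_increase",
    "inverted_to_positive",
    "accelerated_decline",
    "alleviated_increase",
    "inverted_to_negative",
    "none",
)

MODERATOR_MODES = ("large_pa", "post_establishment", "strict_iucn", "exclude_nb")


@dataclass
class SpeciesResponse:
    species_id: str
    effect_mean: float
    effect_lo: float  # 5% posterior quantile
    effect_hi: float  # 95% posterior quantile
    support: float
    response_class: str
    process_category: str


def classify_response(
    draws: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> tuple[str, float]:
    """Response class and support from posterior draws of the interaction.

    support = max(P(beta_int > 0), P(beta_int < 0)); the class is positive/
    negative when support >= threshold (inclusive boundary), else none.
    Constant draws are classified by sign with support 1.
    """
    draws = np.asarray(draws, float)
    if draws.size < 100:
        raise ValueError("need at least 100 posterior draws")
    p_pos = float(np.mean(draws > 0))
    p_neg = float(np.mean(draws < 0))
    support = max(p_pos, p_neg)
    if np.ptp(draws) == 0:
        sign = np.sign(draws[0])
        cls = "positive" if sign > 0 else ("negative" if sign < 0 else "none")
        return cls, 1.0
    if p_pos >= threshold:
        return "positive", support
    if p_neg >= threshold:
        return "negative", support
    return "none", support


def classify_process(
    beta_year_draws: np.ndarray, beta_int_draws: np.ndarray, response_class: str
) -> str:
    """Six-way process category from posterior-mean outside/inside slopes.

    Exactly-zero mean slopes are tie-broken as non-negative (logged), so a
    responding species always lands in one of the six categories.
    """
    if response_class == "none":
        return "none"
    s_out = float(np.mean(beta_year_draws))
    s_in = float(np.mean(beta_year_draws) + np.mean(beta_int_draws))
    if s_out == 0.0 or s_in == 0.0:
        logger.info("exactly zero posterior-mean slope; tie-broken as non-negative")
    out_neg = s_out < 0
    in_neg = s_in < 0
    if response_class == "positive":
        if out_neg and in_neg:
            return "alleviated_decline"
        if not out_neg and not in_neg:
            return "accelerated_increase"
        return "inverted_to_positive"  # declining outside, increasing inside
    # negative response, mirrored
    if out_neg and in_neg:
        return "accelerated_decline"
    if not out_neg and not in_neg:
        return "alleviated_increase"
    return "inverted_to_negative"  # increasing outside, declining inside


def classify_species(
    beta_int_draws: np.ndarray,
    beta_year_draws: np.ndarray,
    species_ids: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-species response table from (draws, species) posterior arrays."""
    beta_int_draws = np.asarray(beta_int_draws, float)
    beta_year_draws = np.asarray(beta_year_draws, float)
    rows = []
    for j, sp in enumerate(species_ids):
        d_int = beta_int_draws[:, j]
        cls, support = classify_response(d_int, threshold)
        proc = classify_process(beta_year_draws[:, j], d_int, cls)
        rows.append(
            {
                "species_id": sp,
                "effect_mean": float(d_int.mean()),
                "effect_lo": float(np.quantile(d_int, 0.05)),
                "effect_hi": float(np.quantile(d_int, 0.95)),
                "support": support,
                "response_class": cls,
                "process_category": proc,
            }
        )
    return pd.DataFrame(rows)


def aggregate(
    responses: pd.DataFrame, taxon_labels: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-taxon percentages of positive/negative/none responses and
    per-process counts.  Without labels all species form one taxon."""
    df = responses.copy()
    df["taxon"] = (
        df["species_id"].map(taxon_labels) if taxon_labels is not None else "all"
    )
    rows = []
    for taxon, grp in df.groupby("taxon"):
        n = len(grp)
        if n == 0:
            continue
        row = {"taxon": taxon, "n_species": n}
        for cls in RESPONSE_CLASSES:
            row[f"pct_{cls}"] = 100.0 * float((grp["response_class"] == cls).sum()) / n
        for cat in PROCESS_CATEGORIES:
            row[f"n_{cat}"] = int((grp["process_category"] == cat).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def moderator_subset(
    design: MatchedDesign,
    protection: pd.DataFrame,
    zones: pd.Series,
    mode: str,
) -> tuple[MatchedDesign, Optional[str]]:
    """Restrict the matched design for a moderator analysis.

    Modes: ``large_pa`` keeps pairs whose attributed PA exceeds the median
    size across protected sites; ``strict_iucn`` keeps pairs in the
    strictest IUCN category present; ``exclude_nb`` drops the North Boreal
    stratum; ``post_establishment`` leaves the pairs intact and returns a
    window directive for :func:`paimpact.trendmodel.build_design`.  Matched
    pairs are always kept or dropped together.
    """
    if mode not in MODERATOR_MODES:
        raise ValueError(f"unknown moderator mode {mode!r}")
    prot = protection.set_index("site_id")
    window = None
    if mode == "post_establishment":
        kept = list(design.pairs)
        window = "post_establishment"
    elif mode == "large_pa":
        sizes = prot.loc[[t for t, _ in design.pairs], "size_ha"].astype(float)
        median = float(np.median(sizes.dropna()))
        kept = [(t, c) for t, c in design.pairs if float(prot.loc[t, "size_ha"]) > median]
    elif mode == "strict_iucn":
        from .config import IUCN_CATEGORIES

        cats = prot.loc[[t for t, _ in design.pairs], "iucn_cat"]
        present = [c for c in IUCN_CATEGORIES if (cats == c).any()]
        if not present:
            raise ValueError("no IUCN categories on protected sites")
        strictest = present[0]
        kept = [(t, c) for t, c in design.pairs if prot.loc[t, "iucn_cat"] == strictest]
    else:  # exclude_nb
        kept = [
            (t, c)
            for t, c in design.pairs
            if zones[t] != "NB" and zones[c] != "NB"
        ]
    if not kept:
        raise ValueError(
            f"moderator {mode!r} leaves no pairs (of {design.n_matched} matched)"
        )
    sub = MatchedDesign(
        pairs=kept,
        method=design.method,
        caliper_multiplier=design.caliper_multiplier,
        balance=design.balance,
        n_treated_total=design.n_treated_total,
    )
    logger.info("moderator %s: %d of %d pairs retained", mode, len(kept), design.n_matched)
    return sub, window
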