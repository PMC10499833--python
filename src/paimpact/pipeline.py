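"""Reproducible staged pipeline: simulate -> assign -> match -> fit ->
classify -> moderate -> traits.

Each stage reads its inputs from the preceding stage's files inside one
run directory and writes immutable outputs plus a ``<stage>.done`` marker,
so a partial rerun resumes from the first incomplete stage.  A manifest
records stage order, output checksums, versions and wall-clock times.
All randomness flows from the run config's seeds via named substreams.
"""

from __future__ import annotations

import hashlib
import logging
import time
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import io, matching, synthdata, trendmodel
from . import traitsphylo
from .config import MCMCSettings, RunConfig, substream
from .geoassign import protection_table
from .trendmodel import Priors

logger = logging.getLogger(__name__)

STAGES = ("simulate", "assign", "match", "fit", "classify", "moderate", "traits")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _design_effort(sites_table: pd.DataFrame, taxon: str) -> Optional[pd.Series]:
    """Effort covariate for the trend model: log effort for birds/mammals,
    log lake size for phytoplankton, none for plants."""
    df = sites_table.set_index("site_id")
    if taxon in ("birds", "mammals"):
        return df["effort"].astype(float)
    if taxon == "phytoplankton":
        return df["lake_size_ha"].astype(float)
    return None


def _build_design_for_sites(
    run_dir: Path,
    config: RunConfig,
    site_ids: Sequence[str],
    subset_window: Optional[str] = None,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> trendmodel.TrendDesign:
    records = io.read_occurrences(run_dir / "simulate" / "occurrences.tsv")
    records = records[records["site_id"].isin(set(site_ids))].reset_index(drop=True)
    records = trendmodel.filter_species(records)
    protection = io.read_table(run_dir / "assign" / "protection.tsv")
    sites_table = io.read_table(run_dir / "simulate" / "sites.tsv")
    zones = sites_table.set_index("site_id")["vegetation_zone"]
    taxon = config.sim.taxon_group
    return trendmodel.build_design(
        records,
        protection,
        zones,
        effort=_design_effort(sites_table, taxon),
        subset_window=subset_window,
        pairs=pairs,
        include_year_re=(taxon != "plants"),
    )


def _save_fit(fit: trendmodel.TrendModelFit, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out_dir / "posterior.npz",
        beta=fit.beta,
        mu=fit.mu,
        V=fit.V,
        site_re=fit.site_re,
        year_re=fit.year_re,
        sigma2_site=fit.sigma2_site,
        sigma2_year=fit.sigma2_year,
        pred_mean=fit.pred_mean,
    )
    io.write_json(
        {
            "parameters": ["beta", "mu", "V", "site_re", "year_re", "sigma2_site", "sigma2_year"],
            "colnames": fit.colnames,
            "species_ids": fit.species_ids,
            "n_chains": int(fit.beta.shape[0]),
            "n_retain": int(fit.beta.shape[1]),
        },
        out_dir / "posterior_manifest.json",
    )
    io.write_table(fit.psrf_table(), out_dir / "psrf.tsv")
    io.write_table(trendmodel.fit_metrics(fit), out_dir / "metrics.tsv")


def _classify_from_fit_dir(fit_dir: Path, threshold: float) -> pd.DataFrame:
    import json

    with open(fit_dir / "posterior_manifest.json") as fh:
        man = json.load(fh)
    arr = np.load(fit_dir / "posterior.npz")
    beta = arr["beta"]  # (chains, draws, p, S)
    cols = man["colnames"]
    S = len(man["species_ids"])
    b_int = beta[:, :, cols.index("prot_x_year"), :].reshape(-1, S)
    b_year = beta[:, :, cols.index("year_rescaled"), :].reshape(-1, S)
    return classify_mod.classify_species(b_int, b_year, man["species_ids"], threshold)


def run(config: RunConfig, out_dir: Optional[Path] = None, stages: Optional[Sequence[str]] = None) -> Path:
    """Execute the pipeline; returns the run directory.

    ``stages`` restricts execution (defaults to all enabled stages);
    completed stages (marker file present) are never recomputed.
    """
    run_dir = Path(out_dir if out_dir is not None else config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    enabled = list(STAGES)
    if not config.run_traits:
        enabled.remove("traits")
    if not config.moderator_modes:
        enabled.remove("moderate")
    todo = [s for s in enabled if stages is None or s in stages]

    manifest: dict = {"stages": [], "seed": config.seed, "package_version": _pkg_version("paimpact")}
    for stage in todo:
        marker = run_dir / f"{stage}.done"
        t0 = time.perf_counter()
        if marker.exists():
            manifest["stages"].append({"stage": stage, "skipped": True})
            continue
        try:
            _STAGE_FUNCS[stage](run_dir, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        marker.write_text("ok\n")
        manifest["stages"].append(
            {"stage": stage, "skipped": False, "wall_clock_s": round(time.perf_counter() - t0, 3)}
        )

    checksums = {
        str(p.relative_to(run_dir)): _checksum(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json",)
    }
    manifest["checksums"] = checksums
    io.write_json(manifest, run_dir / "manifest.json")
    return run_dir


def simulate_matched_dataset(
    sim: "synthdata.SimulationConfig",
    caliper: float = 0.25,
    method: str = "auto",
    max_pairs: Optional[int] = None,
    min_coverage: float = 0.0,
):
    """In-memory shortcut: landscape -> protection -> matching -> occurrences.

    Returns a dict with sites, pas, protection, truth, matched design,
    occurrence records restricted to matched sites, and the assembled
    :class:`~paimpact.trendmodel.TrendDesign` — the study-design inputs a
    trend-model analysis starts from.  ``max_pairs`` caps the design size.
    """
    sites, pas = synthdata.generate_landscape(sim)
    protection = protection_table(sites, pas, min_coverage=min_coverage)
    tree_seed = int(substream(sim.seed, "tree").integers(2**31 - 1))
    truth, _, _ = synthdata.generate_community(sim, tree_seed)
    calendar = synthdata.sample_calendar(sim, [s.site_id for s in sites])
    mean_year = calendar.groupby("site_id")["year"].mean()
    for s in sites:
        s.mean_survey_year = float(mean_year[s.site_id])
    frame = io.sites_frame(sites).merge(protection[["site_id", "protected"]], on="site_id")
    design = matching.build_matched_design(
        frame, sim.taxon_group, method=method, caliper_multiplier=caliper
    )
    pairs = design.pairs if max_pairs is None else design.pairs[:max_pairs]
    design = matching.MatchedDesign(
        pairs=pairs,
        method=design.method,
        caliper_multiplier=design.caliper_multiplier,
        balance=design.balance,
        n_treated_total=design.n_treated_total,
    )
    ids = set(design.site_ids)
    matched_sites = [s for s in sites if s.site_id in ids]
    records = synthdata.simulate_occurrences(
        matched_sites, truth, sim, protection, calendar[calendar["site_id"].isin(ids)]
    )
    records = trendmodel.filter_species(records)
    taxon = sim.taxon_group
    sites_table = io.sites_frame(sites)
    trend_design = trendmodel.build_design(
        records,
        protection,
        sites_table.set_index("site_id")["vegetation_zone"],
        effort=_design_effort(sites_table, taxon),
        include_year_re=(taxon != "plants"),
    )
    return {
        "sites": sites,
        "pas": pas,
        "protection": protection,
        "truth": truth,
        "matched_design": design,
        "records": records,
        "trend_design": trend_design,
        "sites_table": sites_table,
    }


def _stage_simulate(run_dir: Path, config: RunConfig) -> None:
    out = run_dir / "simulate"
    out.mkdir(exist_ok=True)
    sim = config.sim
    sites, pas = synthdata.generate_landscape(sim)
    tree_seed = int(substream(sim.seed, "tree").integers(2**31 - 1))
    truth, _, _ = synthdata.generate_community(sim, tree_seed)
    protection = protection_table(sites, pas, min_coverage=config.min_coverage)
    calendar = synthdata.sample_calendar(sim, [s.site_id for s in sites])
    mean_year = calendar.groupby("site_id")["year"].mean()
    for s in sites:
        s.mean_survey_year = float(mean_year[s.site_id])
    records = synthdata.simulate_occurrences(sites, truth, sim, protection, calendar)
    io.write_sites(sites, out / "sites.tsv", out / "sites.geojson")
    io.write_pas(pas, out / "pas.geojson")
    io.write_table(calendar, out / "calendar.tsv")
    io.write_table(records, out / "occurrences.tsv")
    io.write_truth(truth, out / "truth")
    logger.info("simulate: %d sites, %d PAs, %d records", len(sites), len(pas), len(records))


def _stage_assign(run_dir: Path, config: RunConfig) -> None:
    out = run_dir / "assign"
    out.mkdir(exist_ok=True)
    sites = io.read_sites(run_dir / "simulate" / "sites.tsv", run_dir / "simulate" / "sites.geojson")
    pas = io.read_pas(run_dir / "simulate" / "pas.geojson")
    protection = protection_table(sites, pas, min_coverage=config.min_coverage)
    io.write_table(protection, out / "protection.tsv")
    logger.info("assign: %d of %d sites protected", int(protection["protected"].sum()), len(protection))


def _stage_match(run_dir: Path, config: RunConfig) -> None:
    out = run_dir / "match"
    out.mkdir(exist_ok=True)
    sites_table = io.read_table(run_dir / "simulate" / "sites.tsv")
    protection = io.read_table(run_dir / "assign" / "protection.tsv")
    frame = sites_table.merge(protection[["site_id", "protected"]], on="site_id")
    design = matching.build_matched_design(
        frame, config.sim.taxon_group, method=config.match_method, caliper_multiplier=config.caliper
    )
    io.write_table(design.to_frame(), out / "pairs.tsv")
    io.write_table(design.balance, out / "balance.tsv")
    long = design.balance.melt(id_vars="covariate", var_name="when", value_name="smd")
    io.write_table(long, out / "balance_long.tsv")
    io.write_json(
        {
            "method": design.method,
            "caliper_multiplier": design.caliper_multiplier,
            "n_treated_total": design.n_treated_total,
            "n_matched": design.n_matched,
            "mean_after_smd": design.mean_after_smd,
        },
        out / "matching_summary.json",
    )
    logger.info("match: %d/%d treated matched (%s)", design.n_matched, design.n_treated_total, design.method)


def _load_pairs(run_dir: Path) -> list[tuple[str, str]]:
    pairs = io.read_table(run_dir / "match" / "pairs.tsv")
    return list(pairs.itertuples(index=False, name=None))


def _stage_fit(run_dir: Path, config: RunConfig) -> None:
    out = run_dir / "fit"
    pairs = _load_pairs(run_dir)
    site_ids = [s for pair in pairs for s in pair]
    design = _build_design_for_sites(run_dir, config, site_ids)
    mcmc = MCMCSettings(**{**config.mcmc.__dict__, "seed": config.seed})
    fit = trendmodel.fit(design, mcmc, Priors())
    _save_fit(fit, out)
    logger.info("fit: %d species, %d units, max PSRF %.3f", design.n_species, design.n_units, fit.max_psrf())


def _stage_classify(run_dir: Path, config: RunConfig) -> None:
    out = run_dir / "classify"
    out.mkdir(exist_ok=True)
    responses = _classify_from_fit_dir(run_dir / "fit", config.support_threshold)
    io.write_table(responses, out / "responses.tsv")
    summary = classify_mod.aggregate(responses)
    taxon = config.sim.taxon_group
    summary["taxon"] = taxon
    io.write_table(summary, out / "summary.tsv")
    io.write_json(
        {"per_taxon": summary.to_dict(orient="records"), "threshold": config.support_threshold},
        out / "summary.json",
    )


def _stage_moderate(run_dir: Path, config: RunConfig) -> None:
    sites_table = io.read_table(run_dir / "simulate" / "sites.tsv")
    zones = sites_table.set_index("site_id")["vegetation_zone"]
    protection = io.read_table(run_dir / "assign" / "protection.tsv")
    pairs = _load_pairs(run_dir)
    base = matching.MatchedDesign(pairs=pairs, method="propensity", caliper_multiplier=config.caliper)
    for mode in config.moderator_modes:
        out = run_dir / f"moderate_{mode}"
        out.mkdir(exist_ok=True)
        sub, window = classify_mod.moderator_subset(base, protection, zones, mode)
        design = _build_design_for_sites(
            run_dir, config, sub.site_ids, subset_window=window, pairs=sub.pairs
        )
        mcmc = MCMCSettings(**{**config.mcmc.__dict__, "seed": config.seed + 1})
        fit = trendmodel.fit(design, mcmc, Priors())
        _save_fit(fit, out)
        responses = _classify_from_fit_dir(out, config.support_threshold)
        io.write_table(responses, out / "responses.tsv")
        io.write_json(
            {
                "mode": mode,
                "n_pairs": sub.n_matched,
                "per_taxon": classify_mod.aggregate(responses).to_dict(orient="records"),
            },
            out / "summary.json",
        )


def _stage_traits(run_dir: Path, config: RunConfig) -> None:
    out = run_dir / "traits"
    out.mkdir(exist_ok=True)
    responses = io.read_table(run_dir / "classify" / "responses.tsv")
    effects = responses.set_index("species_id")["effect_mean"].astype(float)
    traits = io.read_table(run_dir / "simulate" / "truth" / "traits.tsv")
    newick = (run_dir / "simulate" / "truth" / "tree.nwk").read_text().strip()
    taxon = config.sim.taxon_group
    reg = traitsphylo.trait_regression(effects, traits, taxon)
    table = reg["coefficients"].copy()
    table.insert(0, "taxon", taxon)
    io.write_table(table, out / "trait_regression.tsv")
    sig = traitsphylo.signal_table(newick, effects, taxon, seed=config.seed)
    io.write_table(sig, out / "signal.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "assign": _stage_assign,
    "match": _stage_match,
    "fit": _stage_fit,
    "classify": _stage_classify,
    "moderate": _stage_moderate,
    "traits": _stage_traits,
}
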