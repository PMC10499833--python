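"""Readers and writers for the pipeline's on-disk formats.

Sites are a delimited table plus a GeoJSON geometry file; protected areas
a GeoJSON FeatureCollection; occurrences, protection assignments, matched
pairs, balance tables and truth parameters are delimited tables; trees
are Newick.  Every writer round-trips losslessly through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .geoassign import ProtectedArea, SurveySite
from .synthdata import COVARIATE_NAMES, LAKE_COVARIATE_NAMES, SimulationTruth


def sites_frame(sites: Sequence[SurveySite]) -> pd.DataFrame:
    """Flat site table (one row per site, covariates as columns)."""
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "taxon_group": s.taxon_group,
            "vegetation_zone": s.vegetation_zone,
            "mean_survey_year": s.mean_survey_year,
            "effort": s.effort,
        }
        row.update({name: v for name, v in zip(COVARIATE_NAMES, s.covariates)})
        if s.lake_covariates is not None:
            row.update({name: v for name, v in zip(LAKE_COVARIATE_NAMES, s.lake_covariates)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_sites(sites: Sequence[SurveySite], table_path: Path, geojson_path: Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"site_id": s.site_id},
            "geometry": mapping(s.geometry),
        }
        for s in sites
    ]
    sites_frame(sites).to_csv(table_path, sep="\t", index=False)
    with open(geojson_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_sites(table_path: Path, geojson_path: Path) -> list[SurveySite]:
    table = pd.read_csv(table_path, sep="\t")
    with open(geojson_path) as fh:
        gj = json.load(fh)
    geoms = {f["properties"]["site_id"]: shape(f["geometry"]) for f in gj["features"]}
    sites = []
    for _, row in table.iterrows():
        lake = None
        if all(c in table.columns for c in LAKE_COVARIATE_NAMES) and not np.isnan(
            row[LAKE_COVARIATE_NAMES[0]]
        ):
            lake = row[LAKE_COVARIATE_NAMES].to_numpy(float)
        sites.append(
            SurveySite(
                site_id=row["site_id"],
                taxon_group=row["taxon_group"],
                geometry=geoms[row["site_id"]],
                vegetation_zone=row["vegetation_zone"],
                covariates=row[COVARIATE_NAMES].to_numpy(float),
                mean_survey_year=float(row["mean_survey_year"]),
                effort=float(row["effort"]),
                lake_covariates=lake,
            )
        )
    return sites


def write_pas(pas: Sequence[ProtectedArea], path: Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "pa_id": pa.pa_id,
                "size_ha": pa.size_ha,
                "iucn_cat": pa.iucn_category,
                "year_established": pa.year_established,
            },
            "geometry": mapping(pa.polygon),
        }
        for pa in pas
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_pas(path: Path) -> list[ProtectedArea]:
    with open(path) as fh:
        gj = json.load(fh)
    return [
        ProtectedArea(
            pa_id=f["properties"]["pa_id"],
            polygon=shape(f["geometry"]),
            size_ha=float(f["properties"]["size_ha"]),
            iucn_category=f["properties"]["iucn_cat"],
            year_established=int(f["properties"]["year_established"]),
        )
        for f in gj["features"]
    ]


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def read_occurrences(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["occ"] = df["occ"].astype(int)
    return df


def abundance_to_occurrence(records: pd.DataFrame, column: str = "abundance") -> pd.DataFrame:
    """Convert abundance records to 0/1 occurrences (any positive count)."""
    out = records.copy()
    out["occ"] = (out[column].astype(float) > 0).astype(int)
    return out.drop(columns=[column])


def write_truth(truth: SimulationTruth, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = pd.DataFrame(
        {
            "species_id": truth.species_ids,
            "beta0": truth.beta0,
            "beta_year": truth.beta_year,
            "beta_int": truth.beta_int,
            "zone_MB": truth.zone_offsets[:, 0],
            "zone_NB": truth.zone_offsets[:, 1],
            "effort_coef": truth.effort_coef,
        }
    )
    write_table(species, out_dir / "truth_species.tsv")
    truth.site_re.rename("site_re").rename_axis("site_id").reset_index().to_csv(
        out_dir / "truth_site_re.tsv", sep="\t", index=False
    )
    truth.year_re.rename("year_re").rename_axis("year").reset_index().to_csv(
        out_dir / "truth_year_re.tsv", sep="\t", index=False
    )
    write_table(truth.traits, out_dir / "traits.tsv")
    (out_dir / "tree.nwk").write_text(truth.tree_newick + "\n")


def read_truth(out_dir: Path) -> SimulationTruth:
    out_dir = Path(out_dir)
    species = read_table(out_dir / "truth_species.tsv")
    site_re = pd.read_csv(out_dir / "truth_site_re.tsv", sep="\t").set_index("site_id")["site_re"]
    year_re = pd.read_csv(out_dir / "truth_year_re.tsv", sep="\t").set_index("year")["year_re"]
    return SimulationTruth(
        species_ids=list(species["species_id"]),
        beta0=species["beta0"].to_numpy(),
        beta_year=species["beta_year"].to_numpy(),
        beta_int=species["beta_int"].to_numpy(),
        zone_offsets=species[["zone_MB", "zone_NB"]].to_numpy(),
        effort_coef=species["effort_coef"].to_numpy(),
        site_re=site_re,
        year_re=year_re,
        traits=read_table(out_dir / "traits.tsv"),
        tree_newick=(out_dir / "tree.nwk").read_text().strip(),
    )


def write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
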