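"""Protection-status assignment from taxon-specific buffers and PA polygons.

A survey site counts as *protected* when a taxon-specific buffer around
its survey geometry overlaps any protected-area polygon with positive
area.  Buffer conventions follow the monitoring schemes: 500 m around
bird line transects, a disc extending 500 m beyond the vertices of
mammal wildlife triangles, a 100 m disc around plant plots, and the lake
polygon itself for phytoplankton.  All geometry is planar with metre
units; no geodesic computation is attempted at study scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .config import IUCN_CATEGORIES, VEGETATION_ZONES

BIRD_BUFFER_M = 500.0
MAMMAL_BUFFER_M = 500.0
PLANT_BUFFER_M = 100.0

TAXON_GROUPS = ("birds", "mammals", "plants", "phytoplankton")


@dataclass
class SurveySite:
    """A monitoring location with geometry, covariates and survey attributes."""

    site_id: str
    taxon_group: str
    geometry: BaseGeometry
    vegetation_zone: str
    covariates: np.ndarray  # 8 land-cover proportions within a 1 km buffer
    mean_survey_year: float
    effort: float
    lake_covariates: Optional[np.ndarray] = None  # phytoplankton only (4 values)

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon_group {self.taxon_group!r}")
        if self.vegetation_zone not in VEGETATION_ZONES:
            raise ValueError(f"unknown vegetation zone {self.vegetation_zone!r}")
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.shape != (8,):
            raise ValueError("covariates must be an 8-vector of proportions")
        if np.any(self.covariates < 0) or np.any(self.covariates > 1):
            raise ValueError("covariate proportions must lie in [0, 1]")
        if self.effort <= 0:
            raise ValueError("effort must be > 0")
        if self.lake_covariates is not None:
            self.lake_covariates = np.asarray(self.lake_covariates, dtype=float)


@dataclass
class ProtectedArea:
    """A protected-area polygon with the attributes used by moderators."""

    pa_id: str
    polygon: Polygon
    size_ha: float
    iucn_category: str
    year_established: int

    def __post_init__(self) -> None:
        if self.size_ha <= 0:
            raise ValueError("PA size must be > 0 ha")
        if self.iucn_category not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {self.iucn_category!r}")

    @property
    def iucn_rank(self) -> int:
        """0 = strictest (category Ia)."""
        return IUCN_CATEGORIES.index(self.iucn_category)


def _triangle_disc(geometry: BaseGeometry, extend: float) -> Polygon:
    """Disc centred at the centroid, reaching ``extend`` beyond the farthest vertex."""
    centre = geometry.centroid
    if geometry.geom_type == "Point":
        circumradius = 0.0
    else:
        coords = (
            geometry.exterior.coords if geometry.geom_type == "Polygon" else geometry.coords
        )
        circumradius = max(centre.distance(Point(c)) for c in coords)
    return centre.buffer(circumradius + extend, quad_segs=64)


def build_buffer(site: SurveySite) -> BaseGeometry:
    """Taxon-specific buffer polygon used to decide protection status."""
    geom = site.geometry
    if geom is None or geom.is_empty or not geom.is_valid:
        raise ValueError(f"site {site.site_id}: invalid geometry")
    if site.taxon_group == "birds":
        return geom.buffer(BIRD_BUFFER_M, quad_segs=64)
    if site.taxon_group == "mammals":
        return _triangle_disc(geom, MAMMAL_BUFFER_M)
    if site.taxon_group == "plants":
        return geom.centroid.buffer(PLANT_BUFFER_M, quad_segs=64)
    if site.taxon_group == "phytoplankton":
        if geom.geom_type != "Polygon":
            raise ValueError("phytoplankton sites must carry a lake polygon")
        return geom
    raise ValueError(f"unknown taxon_group {site.taxon_group!r}")


def assign_protection(
    site: SurveySite,
    buffer: BaseGeometry,
    pas: Sequence[ProtectedArea],
    min_coverage: float = 0.0,
) -> tuple[bool, float, Optional[ProtectedArea]]:
    """Intersect a site buffer with the PA layer.

    Returns ``(protected, coverage_fraction, attributed_pa)``.  The site is
    protected when the combined PA overlap covers more than ``min_coverage``
    of the buffer area (default: any positive overlap).  The attributed PA
    — the source of size/IUCN/establishment-year moderator attributes — is
    the intersecting PA with the largest overlap area.
    """
    if not buffer.is_valid or buffer.area <= 0:
        raise ValueError("buffer polygon invalid or degenerate")
    for pa in pas:
        if not pa.polygon.is_valid:
            raise ValueError(f"PA {pa.pa_id}: invalid polygon")

    overlaps = []
    for pa in pas:
        inter = buffer.intersection(pa.polygon)
        if inter.area > 0:
            overlaps.append((inter.area, pa))
    if not overlaps:
        return False, 0.0, None
    union_area = buffer.intersection(unary_union([pa.polygon for _, pa in overlaps])).area
    coverage = min(union_area / buffer.area, 1.0)
    best = max(overlaps, key=lambda t: t[0])[1]
    protected = coverage > min_coverage
    return protected, coverage, (best if protected else None)


def protection_table(
    sites: Iterable[SurveySite],
    pas: Sequence[ProtectedArea],
    min_coverage: float = 0.0,
) -> pd.DataFrame:
    """Site-level protection assignment for a whole landscape.

    Uses an STR packed R-tree over the PA layer so only candidate PAs with
    overlapping bounding boxes are intersected per site.
    """
    from shapely.strtree import STRtree

    pas = list(pas)
    tree = STRtree([pa.polygon for pa in pas]) if pas else None
    rows = []
    for site in sites:
        buffer = build_buffer(site)
        candidates = [pas[i] for i in tree.query(buffer)] if tree is not None else []
        protected, coverage, pa = assign_protection(site, buffer, candidates, min_coverage)
        rows.append(
            {
                "site_id": site.site_id,
                "protected": bool(protected),
                "coverage_fraction": coverage,
                "pa_id": pa.pa_id if pa else "",
                "size_ha": pa.size_ha if pa else math.nan,
                "iucn_cat": pa.iucn_category if pa else "",
                "year_established": pa.year_established if pa else -1,
            }
        )
    return pd.DataFrame(rows)
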