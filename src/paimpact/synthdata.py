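"""Synthetic landscapes, communities and occurrence records with known truth.

The generator emulates the statistical structure of national monitoring
schemes used for counterfactual protected-area evaluation: survey sites
carrying eight land-cover proportion covariates within a 1 km buffer and
a vegetation-zone stratum (HSB/MB/NB); protected areas placed non-randomly
with respect to land cover and zone, and larger in the north; species with
probit-scale occupancy baselines, year trends, and a sparse spike-and-slab
mixture of protection x year interaction effects; taxon-appropriate survey
geometry and effort; traits and an ultrametric phylogeny.

Every quantity a recovery test needs is returned in :class:`SimulationTruth`.
Random streams are split per operation (landscape / community / occurrence)
so that, e.g., changing ``n_years`` does not perturb the landscape.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
from dendropy.simulate import treesim
import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from shapely.geometry import LineString, Point, Polygon

from .config import IUCN_CATEGORIES, SimulationConfig, substream
from .geoassign import ProtectedArea, SurveySite

DOMAIN_M = 100_000.0  # square study region, metres
ZONE_BREAKS = (0.45, 0.80)  # y-fractions splitting HSB / MB / NB
PA_BASE_RATE = 0.35  # placement probability with zero bias

# Dirichlet concentrations for the 8 land-cover classes + residual class:
# artificial, wetland, water, arable, shrub/herb, broadleaf, conifer, mixed, other
_COVARIATE_ALPHA = {
    "HSB": np.array([1.5, 0.8, 1.2, 2.0, 1.0, 1.5, 2.5, 1.5, 3.0]),
    "MB": np.array([0.8, 1.2, 1.2, 1.0, 1.2, 0.8, 3.5, 1.3, 3.0]),
    "NB": np.array([0.4, 2.0, 1.2, 0.3, 2.0, 0.4, 3.0, 0.7, 3.0]),
}

COVARIATE_NAMES = [
    "artificial",
    "wetland",
    "water",
    "arable",
    "shrub_herb",
    "broadleaf",
    "conifer",
    "mixed_forest",
]
LAKE_COVARIATE_NAMES = ["lake_size_ha", "water_colour", "total_p", "tn_tp"]


@dataclass
class SimulationTruth:
    """True generative parameters, the reference for recovery tests."""

    species_ids: list[str]
    beta0: np.ndarray  # (S,) intercepts, probit scale
    beta_year: np.ndarray  # (S,) year slopes, probit units / year
    beta_int: np.ndarray  # (S,) protection x year interactions
    zone_offsets: np.ndarray  # (S, 2) offsets for MB, NB relative to HSB
    effort_coef: np.ndarray  # (S,) coefficient on standardized log effort
    site_re: pd.Series  # site_id -> random intercept
    year_re: pd.Series  # year -> random intercept
    traits: pd.DataFrame
    tree_newick: str

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


def _site_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _species_ids(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(1, n + 1)]


def _zone_of(y: float) -> str:
    frac = y / DOMAIN_M
    if frac < ZONE_BREAKS[0]:
        return "HSB"
    if frac < ZONE_BREAKS[1]:
        return "MB"
    return "NB"


def _site_geometry(profile: str, x: float, y: float, rng: np.random.Generator):
    """Survey geometry and per-survey effort for one site."""
    if profile == "transect_500m":
        # bird line transect, 3-6 km, two legs with a random bend
        length = rng.uniform(3000.0, 6000.0)
        theta = rng.uniform(0.0, 2 * math.pi)
        bend = theta + rng.uniform(-0.6, 0.6)
        half = length / 2.0
        mid = (x + half * math.cos(theta), y + half * math.sin(theta))
        end = (mid[0] + half * math.cos(bend), mid[1] + half * math.sin(bend))
        return LineString([(x, y), mid, end]), length / 1000.0
    if profile == "triangle_500m":
        # wildlife triangle: 4 km sides, 12 km total transect
        r = 4000.0 / math.sqrt(3.0)  # circumradius of an equilateral 4 km triangle
        theta = rng.uniform(0.0, 2 * math.pi)
        pts = [
            (x + r * math.cos(theta + k * 2 * math.pi / 3), y + r * math.sin(theta + k * 2 * math.pi / 3))
            for k in range(3)
        ]
        effort = 12.0 * rng.uniform(0.8, 1.2)  # km surveyed x days-since-snowfall factor
        return Polygon(pts), effort
    if profile == "lake":
        area_m2 = rng.lognormal(mean=math.log(8e5), sigma=0.8)  # ~ 80 ha lakes
        radius = math.sqrt(area_m2 / math.pi)
        return Point(x, y).buffer(radius, quad_segs=32), 1.0
    if profile in ("point_100m", "point_500m"):
        return Point(x, y), 1.0
    raise ValueError(f"unknown taxon_profile {profile!r}")


def generate_landscape(
    config: SimulationConfig,
) -> tuple[list[SurveySite], list[ProtectedArea]]:
    """Draw survey sites and a biased protected-area layer.

    PA placement probability is ``expit(logit(base) + b*z(artificial-cover)
    + 0.5*b*1[NB])`` with ``b = config.pa_placement_bias``; with ``b = 0``
    placement is completely random.  PAs in the North Boreal zone are drawn
    substantially larger, emulating the northern bias of real networks.
    """
    rng = substream(config.seed, "landscape")
    profile = config.taxon_profile
    taxon = config.taxon_group
    n = config.n_sites
    mid_year = config.first_year + (config.n_years - 1) / 2.0

    xs = rng.uniform(0.0, DOMAIN_M, size=n)
    ys = rng.uniform(0.0, DOMAIN_M, size=n)
    sites: list[SurveySite] = []
    cov0 = np.empty(n)
    for i, sid in enumerate(_site_ids(n)):
        zone = _zone_of(ys[i])
        props = rng.dirichlet(_COVARIATE_ALPHA[zone])[:8]
        geometry, effort = _site_geometry(profile, xs[i], ys[i], rng)
        lake_cov = None
        if profile == "lake":
            lake_cov = np.array(
                [
                    geometry.area / 1e4,  # ha
                    rng.lognormal(math.log(60.0), 0.6),  # water colour, mg Pt/l
                    rng.lognormal(math.log(20.0), 0.7),  # total P, ug/l
                    rng.lognormal(math.log(25.0), 0.5),  # TN:TP
                ]
            )
        cov0[i] = props[0]
        sites.append(
            SurveySite(
                site_id=sid,
                taxon_group=taxon,
                geometry=geometry,
                vegetation_zone=zone,
                covariates=props,
                mean_survey_year=mid_year,
                effort=effort,
                lake_covariates=lake_cov,
            )
        )

    # PA placement seeded at sites, probability tilted by covariate 0 and zone
    z0 = (cov0 - cov0.mean()) / (cov0.std() if cov0.std() > 0 else 1.0)
    bias = config.pa_placement_bias
    base_logit = math.log(PA_BASE_RATE / (1.0 - PA_BASE_RATE))
    is_nb = np.array([s.vegetation_zone == "NB" for s in sites], dtype=float)
    p_place = expit(base_logit + bias * z0 + 0.5 * bias * is_nb)
    placed = rng.uniform(size=n) < p_place

    pas: list[ProtectedArea] = []
    k = 0
    for i, site in enumerate(sites):
        if not placed[i]:
            continue
        k += 1
        size_mult = 6.0 if site.vegetation_zone == "NB" else 1.0
        size_ha = rng.lognormal(math.log(200.0 * size_mult), 0.7)
        radius = math.sqrt(size_ha * 1e4 / math.pi)
        centre = site.geometry.centroid
        jitter = rng.uniform(-0.3 * radius, 0.3 * radius, size=2)
        poly = Point(centre.x + jitter[0], centre.y + jitter[1]).buffer(radius, quad_segs=32)
        pas.append(
            ProtectedArea(
                pa_id=f"PA{k:04d}",
                polygon=poly,
                size_ha=size_ha,
                iucn_category=str(rng.choice(IUCN_CATEGORIES[:5], p=[0.2, 0.1, 0.3, 0.1, 0.3])),
                year_established=int(rng.integers(config.first_year - 30, config.first_year + max(config.n_years // 2, 1))),
            )
        )
    return sites, pas


def simulate_tree(n_tips: int, seed: int) -> str:
    """Ultrametric pure-birth tree with tips ``sp001..spNNN`` as Newick.

    Uses general-sampling-approach conditioning (simulate past the target
    tip count, then sample a moment when exactly ``n_tips`` lineages
    existed) so that no pendant branch has zero length and the
    phylogenetic covariance matrix stays positive definite.
    """
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        gsa_ntax=n_tips + 2,
        rng=_pyrandom.Random(int(seed)),
    )
    for leaf, name in zip(tree.leaf_node_iter(), _species_ids(n_tips)):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label=name)
        else:
            leaf.taxon.label = name
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def generate_community(
    config: SimulationConfig, tree_seed: int
) -> tuple[SimulationTruth, str, pd.DataFrame]:
    """Draw species-level truth, an ultrametric phylogeny and a trait table.

    The interaction effect follows a spike-and-slab mixture: with
    probability ``prop_effect_nonzero`` a species draws its effect from
    ``N(0, effect_sd^2)``, otherwise the effect is exactly zero.  Log body
    size evolves under Brownian motion on the tree (so phylogenetic-signal
    statistics have a known expectation); the species temperature index is
    drawn independently of the tree.
    """
    if config.n_species < 3:
        raise ValueError("need at least 3 species")
    rng = substream(config.seed, "community")
    S = config.n_species
    species = _species_ids(S)
    newick = simulate_tree(S, tree_seed)

    # Brownian trait on the tree: log body size
    vcv, tip_order = tree_vcv(newick)
    order = [tip_order.index(sp) for sp in species]
    vcv = vcv[np.ix_(order, order)]
    depth = float(np.max(np.diag(vcv)))
    scale = 0.5 / math.sqrt(depth) if depth > 0 else 0.5
    chol = np.linalg.cholesky(vcv + 1e-10 * np.eye(S))
    log_size = math.log(20.0) + scale * (chol @ rng.standard_normal(S))

    traits = pd.DataFrame(
        {
            "species_id": species,
            "body_size": np.exp(log_size),
            "sti": rng.normal(4.0, 2.0, size=S),  # degrees C, tree-independent
            "threat": np.where(rng.uniform(size=S) < 0.2, "threatened", "not_threatened"),
        }
    )

    nonzero = rng.uniform(size=S) < config.prop_effect_nonzero
    beta_int = np.where(nonzero, rng.normal(0.0, config.effect_sd, size=S), 0.0)
    truth = SimulationTruth(
        species_ids=species,
        beta0=rng.normal(config.baseline_mean, config.baseline_sd, size=S),
        beta_year=rng.normal(0.0, config.trend_sd, size=S),
        beta_int=beta_int,
        zone_offsets=rng.normal(0.0, 0.3, size=(S, 2)),
        effort_coef=rng.normal(0.3, 0.1, size=S),
        site_re=pd.Series(
            rng.normal(0.0, config.site_re_sd, size=config.n_sites),
            index=_site_ids(config.n_sites),
        ),
        year_re=pd.Series(
            rng.normal(0.0, config.year_re_sd, size=config.n_years),
            index=range(config.first_year, config.first_year + config.n_years),
        ),
        traits=traits,
        tree_newick=newick,
    )
    return truth, newick, traits


def sample_calendar(config: SimulationConfig, site_ids: Sequence[str]) -> pd.DataFrame:
    """Site-year survey calendar with Bernoulli(``revisit_prob``) retention.

    Every site keeps at least one survey year (a random one is forced if
    thinning removed them all), mirroring schemes that survey a subset of
    sites each year.
    """
    rng = substream(config.seed, "calendar")
    years = np.arange(config.first_year, config.first_year + config.n_years)
    rows = []
    for sid in site_ids:
        keep = rng.uniform(size=config.n_years) < config.revisit_prob
        if not keep.any():
            keep[rng.integers(config.n_years)] = True
        for y in years[keep]:
            rows.append((sid, int(y)))
    return pd.DataFrame(rows, columns=["site_id", "year"])


def standardized_log_effort(efforts: pd.Series) -> pd.Series:
    """z-scored log effort; degenerate (constant) effort maps to 0."""
    le = np.log(efforts.astype(float))
    sd = le.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        return le * 0.0
    return (le - le.mean()) / sd


def simulate_occurrences(
    sites: Sequence[SurveySite],
    truth: SimulationTruth,
    config: SimulationConfig,
    protection: pd.DataFrame,
    calendar: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Draw 0/1 occurrence records for sampled site-years.

    ``P(occ=1) = Phi(b0_j + b_year_j*t + b_int_j*t*protected_i + zone
    + effort + site RE + year RE) * detection_per_visit`` with the year
    index ``t`` rescaled so the earliest survey year is 1, matching the
    trend-model design exactly.
    """
    if calendar is None:
        calendar = sample_calendar(config, [s.site_id for s in sites])
    rng = substream(config.seed, "occurrence")
    prot = protection.set_index("site_id")["protected"].astype(bool)

    site_by_id = {s.site_id: s for s in sites}
    eff = pd.Series({s.site_id: s.effort for s in sites})
    z_eff = standardized_log_effort(eff)
    zone_idx = {"HSB": -1, "MB": 0, "NB": 1}  # column of zone_offsets; HSB baseline
    year0 = int(calendar["year"].min())

    missing = set(calendar["site_id"]) - set(site_by_id)
    if missing:
        raise ValueError(f"calendar references unknown sites: {sorted(missing)[:5]}")

    records = []
    sp_idx = np.arange(truth.n_species)
    for sid, year in calendar.itertuples(index=False):
        site = site_by_id[sid]
        t = year - year0 + 1
        zi = zone_idx[site.vegetation_zone]
        zone_term = truth.zone_offsets[:, zi] if zi >= 0 else 0.0
        lp = (
            truth.beta0
            + truth.beta_year * t
            + truth.beta_int * t * float(prot.get(sid, False))
            + zone_term
            + truth.effort_coef * z_eff[sid]
            + float(truth.site_re.get(sid, 0.0))
            + float(truth.year_re.get(year, 0.0))
        )
        if not np.all(np.isfinite(lp)):
            raise FloatingPointError(f"non-finite linear predictor at site {sid}, year {year}")
        p = ndtr(lp) * config.detection_per_visit
        occ = (rng.uniform(size=truth.n_species) < p).astype(int)
        for j in sp_idx:
            records.append((sid, truth.species_ids[j], year, occ[j], site.effort))
    return pd.DataFrame(records, columns=["site_id", "species_id", "year", "occ", "effort"])


def tree_vcv(newick: str) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic covariance matrix (shared branch length from the root).

    Works for non-ultrametric trees too: ``V[i, j] = (d_i + d_j - d_ij)/2``
    with root-to-tip distances ``d_i`` and patristic distances ``d_ij``.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    tree.calc_node_root_distances()
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.root_distance
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depth[labels[i]]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            V[i, j] = V[j, i] = 0.5 * (depth[labels[i]] + depth[labels[j]] - d)
    return V, labels
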