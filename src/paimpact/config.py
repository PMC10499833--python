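"""Configuration containers for simulation, MCMC and pipeline runs.

All randomness in the package flows from a single integer seed through
named :func:`numpy.random.SeedSequence` substreams (see :func:`substream`),
so that e.g. changing the number of survey years never perturbs the
landscape draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

TAXON_PROFILES = ("point_100m", "point_500m", "transect_500m", "triangle_500m", "lake")

#: Survey-scheme profile -> taxonomic group whose buffer/effort conventions apply.
PROFILE_TAXON = {
    "point_100m": "plants",
    "point_500m": "mammals",
    "transect_500m": "birds",
    "triangle_500m": "mammals",
    "lake": "phytoplankton",
}

VEGETATION_ZONES = ("HSB", "MB", "NB")

#: IUCN protected-area management categories, strictest first.
IUCN_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI")


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic monitoring study.

    The defaults define the study conditions used throughout the test
    suite: a bird-transect-style scheme with biased PA placement and a
    sparse spike-and-slab mixture of protection x year interaction
    effects on the probit scale.
    """

    n_sites: int = 300
    n_species: int = 60
    n_years: int = 20
    taxon_profile: str = "transect_500m"
    #: spike-and-slab mixture weight: probability that a species has a
    #: nonzero protection x year interaction effect.
    prop_effect_nonzero: float = 0.3
    #: slab SD of the interaction effect (probit units / year).
    effect_sd: float = 0.05
    #: SD of species-specific year slopes (probit units / year).
    trend_sd: float = 0.02
    #: mean/SD of species baseline occupancy intercepts (probit units).
    baseline_mean: float = -0.5
    baseline_sd: float = 0.7
    site_re_sd: float = 0.3
    year_re_sd: float = 0.1
    #: log-odds shift of PA placement probability per SD of the first
    #: land-cover covariate (non-random placement; 0 = unbiased).
    pa_placement_bias: float = 1.0
    detection_per_visit: float = 1.0
    #: probability that a given site-year combination is actually surveyed
    #: (unbalanced revisit calendars, as in real monitoring schemes).
    revisit_prob: float = 0.8
    first_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.taxon_profile not in TAXON_PROFILES:
            raise ValueError(f"unknown taxon_profile {self.taxon_profile!r}")
        for name in ("n_sites", "n_species", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("prop_effect_nonzero", "revisit_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.detection_per_visit <= 1.0:
            raise ValueError("detection_per_visit must be in (0, 1]")
        for name in ("effect_sd", "trend_sd", "baseline_sd", "site_re_sd", "year_re_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isfinite(self.pa_placement_bias):
            raise ValueError("pa_placement_bias must be finite")

    @property
    def taxon_group(self) -> str:
        return PROFILE_TAXON[self.taxon_profile]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        return cls(**d)


@dataclass
class MCMCSettings:
    """Gibbs-sampler schedule. ``n_retain`` draws per chain are kept after
    ``n_burn`` burn-in iterations, taking every ``n_thin``-th draw."""

    n_chains: int = 4
    n_burn: int = 500
    n_thin: int = 10
    n_retain: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if min(self.n_burn, self.n_retain) < 0 or self.n_thin < 1:
            raise ValueError("invalid MCMC schedule")


@dataclass
class RunConfig:
    """Full pipeline configuration: stage toggles plus module parameters."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    caliper: float = 0.25
    match_method: str = "auto"  # propensity | mahalanobis | auto
    min_coverage: float = 0.0
    support_threshold: float = 0.90
    moderator_modes: tuple[str, ...] = ()
    run_traits: bool = True
    seed: int = 0
    out_dir: str = "run"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["moderator_modes"] = list(self.moderator_modes)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        d["sim"] = SimulationConfig.from_dict(d.get("sim", {}))
        d["mcmc"] = MCMCSettings(**d.get("mcmc", {}))
        d["moderator_modes"] = tuple(d.get("moderator_modes", ()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Named child RNG stream of a global seed.

    Names are hashed stably (not with Python's salted ``hash``) so that
    the same (seed, name path) always yields the same stream.
    """
    keys = [abs(hash_name(n)) if isinstance(n, str) else int(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(keys)))


def hash_name(name: str) -> int:
    h = 2166136261
    for byte in name.encode():
        h = ((h ^ byte) * 16777619) % (1 << 32)
    return h
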