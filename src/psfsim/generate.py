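"""Synthetic data with the statistical structure of the common-garden experiment
and the landscape vegetation survey.

The original plot-level tables are not archived in a public repository, so the
rest of the pipeline is exercised against generated tables that encode the
reported structure: five conditioned soil types crossed with a three-species
native and a three-species non-native community (15-31 replicate plots per
cell), with the native community suppressed on *C. diffusa* soil (cover 0.48x
the other soils) and the non-native community suppressed on *P. spicata* soil
(0.45x); and a 25-site, four-transect, seven-year survey in which natives
dominate never-tilled ground and non-natives dominate abandoned fields.

Default community totals place the fast-establishing ruderal non-natives
(35% cover after three growing seasons) above the slow-growing native
bunchgrasses (26%); the suppression ratios are applied on top of those
baselines.  Per-species cover within a community is split equally by default
(the experiment reported community totals, not a per-species breakdown); a
landscape-abundance-proportional split is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .species import COMMUNITIES, LANDSCAPE_COVER, SOIL_TYPES, SPECIES, community_members

logger = logging.getLogger(__name__)

#: Fractional community cover retained on the suppressive "other" soil:
#: native cover was 52% smaller on CEDI soil, non-native cover 55% smaller on
#: PSSP soil, than on the remaining soils on average.
NATIVE_SUPPRESSION = 0.48
NONNATIVE_SUPPRESSION = 0.45

DEFAULT_NATIVE_TOTAL = 26.0  # percent cover on non-suppressive soils
DEFAULT_NONNATIVE_TOTAL = 35.0

REPLICATE_RANGE = (15, 31)
DEFAULT_REPLICATES = 25


def default_mean_cover() -> dict[tuple[str, str], float]:
    """Expected total community percent cover per (community, soil_type) cell."""
    means: dict[tuple[str, str], float] = {}
    for soil in SOIL_TYPES:
        means[("native", soil)] = DEFAULT_NATIVE_TOTAL * (
            NATIVE_SUPPRESSION if soil == "CEDI" else 1.0
        )
        means[("non-native", soil)] = DEFAULT_NONNATIVE_TOTAL * (
            NONNATIVE_SUPPRESSION if soil == "PSSP" else 1.0
        )
    return means


def equal_split() -> dict[str, float]:
    """Equal within-community split: each species carries a third of its community."""
    return {code: 1.0 / 3.0 for code in SPECIES}


def landscape_split() -> dict[str, float]:
    """Within-community split proportional to landscape percent cover."""
    split: dict[str, float] = {}
    for community in COMMUNITIES:
        members = community_members(community)
        total = sum(LANDSCAPE_COVER[m] for m in members)
        for m in members:
            split[m] = LANDSCAPE_COVER[m] / total
    return split


@dataclass
class GeneratorConfig:
    """Parameters of the experiment-table generator.

    dispersion is the standard deviation (percent-cover points) of the
    community-total noise; 0 gives the noise-free limit.  noise_model is
    "truncnorm" (normal truncated to [0, 100]) or "beta" (matched mean/SD on
    the bounded support).
    """

    mean_cover: dict[tuple[str, str], float] = field(default_factory=default_mean_cover)
    within_community_split: dict[str, float] = field(default_factory=equal_split)
    replicates: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            (c, s): DEFAULT_REPLICATES for c in COMMUNITIES for s in SOIL_TYPES
        }
    )
    noise_model: str = "truncnorm"
    dispersion: float = 5.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.noise_model not in ("truncnorm", "beta"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for community in COMMUNITIES:
            members = community_members(community)
            total = sum(self.within_community_split[m] for m in members)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"within_community_split for {community} sums to {total}, not 1"
                )
        for (community, soil), mean in self.mean_cover.items():
            if not 0.0 <= mean <= 100.0:
                raise ValueError(f"mean_cover[{community}, {soil}] = {mean} outside [0, 100]")
        lo, hi = REPLICATE_RANGE
        for cell, n in self.replicates.items():
            if not lo <= n <= hi:
                raise ValueError(f"replicates[{cell}] = {n} outside [{lo}, {hi}]")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "GeneratorConfig":
        """Build a config from a plain (e.g. YAML-loaded) mapping."""
        kwargs: dict = {}
        if "mean_cover" in raw:
            kwargs["mean_cover"] = {
                (c, s): float(v)
                for c, soils in raw["mean_cover"].items()
                for s, v in soils.items()
            }
        if "within_community_split" in raw:
            kwargs["within_community_split"] = {
                k: float(v) for k, v in raw["within_community_split"].items()
            }
        if "replicates" in raw:
            reps = raw["replicates"]
            if isinstance(reps, int):
                kwargs["replicates"] = {
                    (c, s): reps for c in COMMUNITIES for s in SOIL_TYPES
                }
            else:
                kwargs["replicates"] = {
                    (c, s): int(v)
                    for c, soils in reps.items()
                    for s, v in soils.items()
                }
        for key in ("noise_model", "dispersion", "rng_seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _draw_totals(
    rng: np.random.Generator, mean: float, sd: float, size: int, noise_model: str
) -> np.ndarray:
    if sd == 0 or mean == 0:
        return np.full(size, mean)
    if noise_model == "truncnorm":
        a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
        return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    # beta on [0, 100] with matched mean and (approximate) SD
    mu = mean / 100.0
    var = min((sd / 100.0) ** 2, mu * (1 - mu) * 0.999)
    nu = mu * (1 - mu) / var - 1.0
    return 100.0 * rng.beta(mu * nu, (1 - mu) * nu, size=size)


def generate_experiment(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate the plot-level experiment table.

    Returns a wide DataFrame with columns plot_id, soil_type, community and one
    percent-cover column per species code (zero outside the plot's community).
    Each plot's community total is drawn from the noise model around the cell
    mean and split among the community members by within_community_split.
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    rows: list[dict] = []
    for community in COMMUNITIES:
        members = community_members(community)
        prefix = "N" if community == "native" else "X"
        for soil in SOIL_TYPES:
            n = config.replicates[(community, soil)]
            totals = _draw_totals(
                rng, config.mean_cover[(community, soil)], config.dispersion, n,
                config.noise_model,
            )
            for i, total in enumerate(totals):
                row = {
                    "plot_id": f"{prefix}-{soil}-{i + 1:02d}",
                    "soil_type": soil,
                    "community": community,
                }
                for sp in SPECIES:
                    row[sp] = (
                        float(total) * config.within_community_split[sp]
                        if sp in members
                        else 0.0
                    )
                rows.append(row)
    return pd.DataFrame(rows)


#: Transect-mean percent cover (native, non-native) per signed distance class.
#: Negative distances lie in abandoned-agricultural fields.  Values encode the
#: surveyed origin shares (25/75, 36/64, 86/14, 94/6) of the observed total
#: herbaceous target cover (38% in abandoned fields, 43% in never-tilled).
DEFAULT_SURVEY_MEANS: dict[int, tuple[float, float]] = {
    -50: (9.50, 28.50),
    -5: (13.68, 24.32),
    5: (36.98, 6.02),
    50: (40.42, 2.58),
}

DISTANCE_CLASSES: tuple[int, ...] = (-50, -5, 5, 50)


def generate_survey(
    n_sites: int = 25,
    years: int = 7,
    means: Mapping[int, tuple[float, float]] | None = None,
    dispersion: float = 5.0,
    rng_seed: int = 0,
    site_sd: float = 3.0,
) -> pd.DataFrame:
    """Generate the landscape survey table (one row per site x transect x year).

    Columns: site_id, distance_m, year, native_cover, nonnative_cover.
    Records are paired by site: each site carries a random site effect shared
    by all its transects and years, plus residual noise with SD `dispersion`.
    Covers are clipped to [0, 100].
    """
    if means is None:
        means = DEFAULT_SURVEY_MEANS
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    missing = [d for d in DISTANCE_CLASSES if d not in means]
    if missing:
        raise ValueError(f"means missing distance classes {missing}")
    if dispersion < 0 or site_sd < 0:
        raise ValueError("dispersion and site_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    rows: list[dict] = []
    for site in range(1, n_sites + 1):
        site_effect = rng.normal(0.0, site_sd) if site_sd > 0 else 0.0
        for dist in DISTANCE_CLASSES:
            nat_mean, non_mean = means[dist]
            for year in range(1, years + 1):
                nat = nat_mean + site_effect
                non = non_mean + site_effect
                if dispersion > 0:
                    nat += rng.normal(0.0, dispersion)
                    non += rng.normal(0.0, dispersion)
                rows.append(
                    {
                        "site_id": f"S{site:02d}",
                        "distance_m": dist,
                        "year": year,
                        "native_cover": float(np.clip(nat, 0.0, 100.0)),
                        "nonnative_cover": float(np.clip(non, 0.0, 100.0)),
                    }
                )
    return pd.DataFrame(rows)


def write_tables(out_dir: str | Path, config: GeneratorConfig | None = None,
                 survey_kwargs: Mapping | None = None) -> tuple[Path, Path]:
    """Write experiment.csv and survey.csv to out_dir; returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp_path = out / "experiment.csv"
    survey_path = out / "survey.csv"
    generate_experiment(config).to_csv(exp_path, index=False)
    generate_survey(**dict(survey_kwargs or {})).to_csv(survey_path, index=False)
    logger.info("wrote %s and %s", exp_path, survey_path)
    return exp_path, survey_path
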