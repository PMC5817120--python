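"""Derive per-step growth rates and group carrying capacities from plot cover.

Each species is assumed to grow exponentially from seed (ground-cover fraction
I = 0.004) to its observed final cover F over one 55-step growing season, so
its per-step multiplicative rate on a given soil is (F / I)^(1/55).  F is the
mean cover (fraction) that the species attained across the replicate plots of
its community on that soil.  The null (feedback-free) model collapses each
species' five soil-specific rates to the single rate on its "self" soil.

Carrying capacities are estimated per origin group as the mean plus two
standard deviations of plot-level community-total cover, pooled over soils.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .species import NATIVE, SELF_SOIL, SOIL_TYPES, SPECIES, community_members

DEFAULT_STEPS_PER_SEASON = 55
DEFAULT_INITIAL_COVER = 0.004  # ground-cover fraction of a seed


def step_rate(final_cover, initial_cover, steps: int):
    """Per-step multiplicative rate mapping initial_cover to final_cover in `steps` steps.

    Accepts scalars or arrays; pure exponential growth at the returned rate for
    `steps` steps maps I exactly onto F.
    """
    final_cover = np.asarray(final_cover, dtype=float)
    initial_cover = np.asarray(initial_cover, dtype=float)
    if np.any(final_cover <= 0) or np.any(initial_cover <= 0):
        raise ValueError("covers must be > 0 (floor zero observations first)")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    out = np.exp(np.log(final_cover / initial_cover) / steps)
    return float(out) if out.ndim == 0 else out


@dataclass
class RateTable:
    """Per-species, per-soil per-step growth rates plus the null-model rates.

    rates: DataFrame indexed by species code with one column per soil type.
    null_rates: Series indexed by species code (self-soil rate).
    """

    rates: pd.DataFrame
    null_rates: pd.Series
    steps_per_season: int = DEFAULT_STEPS_PER_SEASON
    initial_cover: float = DEFAULT_INITIAL_COVER

    def validate(self) -> None:
        if (self.rates <= 0).any().any():
            raise ValueError("all rates must be > 0")
        missing = set(self.rates.index) - set(self.null_rates.index)
        if missing:
            raise ValueError(f"null_rates missing species {sorted(missing)}")

    def collapsed(self) -> "RateTable":
        """Soil-invariant table realising the null model: every soil column of a
        species is replaced by its single self-soil rate."""
        rates = pd.DataFrame(
            {soil: self.null_rates.reindex(self.rates.index) for soil in self.rates.columns}
        )
        return RateTable(rates, self.null_rates.copy(), self.steps_per_season,
                         self.initial_cover)

    def to_csv(self, path: str | Path) -> None:
        out = self.rates.copy()
        out["null_rate"] = self.null_rates.reindex(out.index)
        out.to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path: str | Path, steps_per_season: int = DEFAULT_STEPS_PER_SEASON,
                 initial_cover: float = DEFAULT_INITIAL_COVER) -> "RateTable":
        df = pd.read_csv(path, index_col="species")
        df.index.name = None
        null_rates = df.pop("null_rate")
        return cls(df, null_rates, steps_per_season, initial_cover)


@dataclass(frozen=True)
class CarryingCapacities:
    """Maximum ground-cover fraction each origin group can attain."""

    k_native: float
    k_nonnative: float

    def __post_init__(self) -> None:
        for k in (self.k_native, self.k_nonnative):
            if not 0.0 < k <= 1.0:
                raise ValueError("carrying capacities must lie in (0, 1]")

    def for_group(self, community: str) -> float:
        return self.k_native if community == "native" else self.k_nonnative


def derive_rate_table(
    plots: pd.DataFrame,
    steps_per_season: int = DEFAULT_STEPS_PER_SEASON,
    initial_cover: float = DEFAULT_INITIAL_COVER,
    self_soil: dict[str, str] = SELF_SOIL,
) -> RateTable:
    """Derive the RateTable from the experiment table.

    For each species and soil, F is the mean percent cover of that species
    across the plots of its community on that soil, converted to a ground
    fraction.  Cell means below the seed cover are floored at initial_cover
    (rate 1), so species absent from a soil are static rather than
    instantaneously extinct.
    """
    cells = np.empty((len(SPECIES), len(SOIL_TYPES)))
    for i, sp in enumerate(SPECIES):
        community = "native" if sp in NATIVE else "non-native"
        sub = plots[plots["community"] == community]
        for j, soil in enumerate(SOIL_TYPES):
            vals = sub.loc[sub["soil_type"] == soil, sp]
            if vals.empty:
                raise ValueError(f"no plots for ({sp}, {soil}); cannot derive rate")
            cells[i, j] = max(vals.mean() / 100.0, initial_cover)
    rates = pd.DataFrame(
        step_rate(cells, initial_cover, steps_per_season),
        index=list(SPECIES), columns=list(SOIL_TYPES),
    )
    null_rates = pd.Series(
        {sp: rates.at[sp, self_soil[sp]] for sp in SPECIES}, name="null_rate"
    )
    table = RateTable(rates, null_rates, steps_per_season, initial_cover)
    table.validate()
    return table


def derive_capacities(plots: pd.DataFrame, ddof: int = 1) -> CarryingCapacities:
    """Mean + 2 SD of plot-level community-total cover (fraction), per group.

    The SD pools all plots of a community over soils; ddof=1 (sample SD) by
    default.
    """
    ks: dict[str, float] = {}
    for community in ("native", "non-native"):
        members = list(community_members(community))
        totals = (
            plots.loc[plots["community"] == community, members].sum(axis=1) / 100.0
        )
        if len(totals) < 2:
            raise ValueError(f"need >= 2 plots for community {community}")
        ks[community] = float(totals.mean() + 2.0 * totals.std(ddof=ddof))
    return CarryingCapacities(k_native=ks["native"], k_nonnative=ks["non-native"])
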