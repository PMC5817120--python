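"""Discrete-time community growth model with soil-mediated feedback.

State: the ground-cover fraction of each of the six species plus the
proportion of ground occupied by each cultivated soil type.  Per step each
species multiplies its cover by an effective rate — the soil-proportion-
weighted (additive) mix of its soil-specific rates, or its single self-soil
rate when feedback is switched off.  Cover is then capped: first at the pot
level (total cover of all plants cannot exceed the pot carrying capacity;
proportional rescale), then per origin group (native and non-native totals
cannot exceed their group capacities; proportional rescale within the group).
Soil proportions are refreshed from plant relative abundance once per growing
season (every `soil_update_interval` steps, default 55, i.e. annually), so a
season's growth imprints the next season's soil composition.

The model is fully deterministic; all stochasticity in this package lives in
the synthetic-data generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rates import CarryingCapacities, RateTable
from .species import NATIVE, SOIL_TYPES, SPECIES, SPECIES_TO_SOIL

logger = logging.getLogger(__name__)

DEFAULT_N_STEPS = 165  # 3 growing seasons x 55 steps


@dataclass
class CommunityState:
    """Cover of each species and proportion of each soil type at one step."""

    cover: np.ndarray  # (n_species,) ground-cover fractions
    soil: np.ndarray  # (n_soils,) proportions summing to 1
    step_index: int = 0
    species: tuple[str, ...] = SPECIES
    soil_types: tuple[str, ...] = SOIL_TYPES

    @classmethod
    def from_maps(cls, cover: Mapping[str, float], soil: Mapping[str, float],
                  step_index: int = 0) -> "CommunityState":
        return cls(
            cover=np.array([cover.get(sp, 0.0) for sp in SPECIES], dtype=float),
            soil=np.array([soil.get(s, 0.0) for s in SOIL_TYPES], dtype=float),
            step_index=step_index,
        )

    def cover_map(self) -> dict[str, float]:
        return dict(zip(self.species, self.cover.tolist()))

    def soil_map(self) -> dict[str, float]:
        return dict(zip(self.soil_types, self.soil.tolist()))

    def group_total(self, community: str) -> float:
        mask = _native_mask(self.species) if community == "native" else ~_native_mask(self.species)
        return float(self.cover[mask].sum())

    def validate(self, capacities: CarryingCapacities | None = None,
                 atol: float = 1e-9) -> None:
        if np.any(self.cover < 0):
            raise ValueError("covers must be >= 0")
        if np.any(self.soil < 0) or abs(self.soil.sum() - 1.0) > atol:
            raise ValueError("soil proportions must be >= 0 and sum to 1")
        if capacities is not None:
            if self.group_total("native") > capacities.k_native + atol:
                raise ValueError("native total exceeds k_native")
            if self.group_total("non-native") > capacities.k_nonnative + atol:
                raise ValueError("non-native total exceeds k_nonnative")


def _native_mask(species: Sequence[str]) -> np.ndarray:
    return np.array([sp in NATIVE for sp in species])


@dataclass
class SimulationConfig:
    """Configuration of one model run.

    pot_capacity: total-cover ceiling shared by all plants.  "auto" uses
    max(k_native, k_nonnative); None disables the pot-level cap (leaving only
    the independent group caps).  growth_form "ceiling" realises logistic
    behaviour as exponential growth under hard caps (rates were derived
    assuming pure exponential transit from I to F); "damped" applies a
    (1 - N/K) drag on the group instead, for sensitivity analysis.
    """

    rate_table: RateTable
    capacities: CarryingCapacities
    n_steps: int = DEFAULT_N_STEPS
    feedback: bool = True
    species_to_soil: dict[str, str] = field(default_factory=lambda: dict(SPECIES_TO_SOIL))
    soil_update_interval: int = 55
    pot_capacity: float | None | str = "auto"
    growth_form: str = "ceiling"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.soil_update_interval < 1:
            raise ValueError("soil_update_interval must be >= 1")
        if self.growth_form not in ("ceiling", "damped"):
            raise ValueError(f"unknown growth_form {self.growth_form!r}")
        missing = [sp for sp in self.rate_table.rates.index if sp not in self.species_to_soil]
        if missing:
            raise ValueError(f"species_to_soil missing {missing}")

    def resolved_pot_capacity(self) -> float | None:
        if self.pot_capacity == "auto":
            return max(self.capacities.k_native, self.capacities.k_nonnative)
        return self.pot_capacity

    def rate_matrix(self) -> np.ndarray:
        """(n_species, n_soils) rates in canonical order; collapsed when feedback is off."""
        table = self.rate_table if self.feedback else self.rate_table.collapsed()
        return table.rates.reindex(index=list(SPECIES), columns=list(SOIL_TYPES)).to_numpy()

    def cultivation_matrix(self) -> np.ndarray:
        """(n_soils, n_species) indicator: soil s is cultivated by species i."""
        c = np.zeros((len(SOIL_TYPES), len(SPECIES)))
        for i, sp in enumerate(SPECIES):
            c[SOIL_TYPES.index(self.species_to_soil[sp]), i] = 1.0
        return c


def effective_rate(species: str, state: CommunityState, config: SimulationConfig) -> float:
    """Soil-weighted per-step rate for one species under the current soil mix."""
    if species not in config.rate_table.rates.index:
        raise KeyError(f"species {species!r} missing from rate table")
    i = SPECIES.index(species)
    return float(config.rate_matrix()[i] @ state.soil)


def apply_capacity(
    proposed_cover: Mapping[str, float], capacities: CarryingCapacities
) -> dict[str, float]:
    """Cap each origin group's total at its carrying capacity.

    Groups exceeding their K are rescaled proportionally (preserving
    within-group cover ratios) so the group total equals K exactly; groups at
    or below K are untouched.  A zero-total group is returned unchanged.
    """
    cover = np.array([proposed_cover.get(sp, 0.0) for sp in SPECIES], dtype=float)
    if np.any(cover < 0):
        raise ValueError("proposed covers must be >= 0")
    capped = _apply_group_caps(cover, capacities)
    return dict(zip(SPECIES, capped.tolist()))


def _apply_group_caps(cover: np.ndarray, capacities: CarryingCapacities) -> np.ndarray:
    out = cover.copy()
    mask = _native_mask(SPECIES)
    for group_mask, k in ((mask, capacities.k_native), (~mask, capacities.k_nonnative)):
        total = out[group_mask].sum()
        if total > k:
            out[group_mask] *= k / total
    return out


def _apply_pot_cap(cover: np.ndarray, pot_k: float | None) -> np.ndarray:
    if pot_k is None:
        return cover
    total = cover.sum()
    if total > pot_k:
        return cover * (pot_k / total)
    return cover


def update_soils(state: CommunityState, config: SimulationConfig) -> dict[str, float]:
    """Soil proportions implied by current plant relative abundance.

    Each soil's proportion is the summed cover of the species cultivating it
    divided by total cover.  With zero total cover the previous proportions
    are retained (and a warning logged).
    """
    total = state.cover.sum()
    if total <= 0:
        logger.warning("total cover is zero at step %d; soils held", state.step_index)
        return state.soil_map()
    soil = config.cultivation_matrix() @ state.cover / total
    return dict(zip(SOIL_TYPES, soil.tolist()))


@dataclass
class Trajectory:
    """Ordered sequence of states from step 0 to n_steps (length n_steps + 1)."""

    states: list[CommunityState]

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> CommunityState:
        return self.states[i]

    @property
    def final(self) -> CommunityState:
        return self.states[-1]

    def cover_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [s.cover for s in self.states], columns=list(SPECIES),
            index=pd.RangeIndex(len(self.states), name="step"),
        )

    def soil_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [s.soil for s in self.states], columns=list(SOIL_TYPES),
            index=pd.RangeIndex(len(self.states), name="step"),
        )

    def to_tidy(self) -> pd.DataFrame:
        """Long table (step, kind, name, value) for CSV export."""
        cov = self.cover_frame().reset_index().melt("step", var_name="name")
        cov["kind"] = "cover"
        soil = self.soil_frame().reset_index().melt("step", var_name="name")
        soil["kind"] = "soil"
        return pd.concat([cov, soil], ignore_index=True)[["step", "kind", "name", "value"]]


def initial_state(
    soil: Mapping[str, float], propagule_cover: float = 0.004
) -> CommunityState:
    """All six species at the propagule cover on a given initial soil mix."""
    if propagule_cover <= 0:
        raise ValueError("propagule_cover must be > 0")
    s = np.array([soil.get(t, 0.0) for t in SOIL_TYPES], dtype=float)
    if np.any(s < 0) or abs(s.sum() - 1.0) > 1e-9:
        raise ValueError("initial soil proportions must be >= 0 and sum to 1")
    return CommunityState(
        cover=np.full(len(SPECIES), propagule_cover, dtype=float), soil=s, step_index=0
    )


def simulate(initial: CommunityState, config: SimulationConfig) -> Trajectory:
    """Run the model for config.n_steps steps and return the full trajectory.

    Per step: grow (cover x effective rate), cap (pot level, then group
    level), and — at season boundaries — refresh soil proportions from the
    plant cover that just grew.  Deterministic and bit-reproducible.
    """
    config.rate_table.validate()
    rate_matrix = config.rate_matrix()
    cultivation = config.cultivation_matrix()
    pot_k = config.resolved_pot_capacity()
    mask = _native_mask(SPECIES)

    cover = initial.cover.astype(float).copy()
    soil = initial.soil.astype(float).copy()
    states = [replace(initial, cover=cover.copy(), soil=soil.copy(), step_index=0)]

    for t in range(1, config.n_steps + 1):
        r = rate_matrix @ soil
        if config.growth_form == "damped":
            for group_mask, k in (
                (mask, config.capacities.k_native),
                (~mask, config.capacities.k_nonnative),
            ):
                drag = max(0.0, 1.0 - cover[group_mask].sum() / k)
                r[group_mask] = 1.0 + (r[group_mask] - 1.0) * drag
        cover = cover * r
        cover = _apply_pot_cap(cover, pot_k)
        cover = _apply_group_caps(cover, config.capacities)
        if t % config.soil_update_interval == 0:
            total = cover.sum()
            if total > 0:
                soil = cultivation @ cover / total
            else:
                logger.warning("total cover is zero at step %d; soils held", t)
        states.append(CommunityState(cover=cover.copy(), soil=soil.copy(), step_index=t))
    return Trajectory(states)
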