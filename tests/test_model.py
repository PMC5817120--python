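"""Community simulator: effective rates, caps, soil tracking, trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import psfsim as ps
from psfsim.model import CommunityState, _apply_pot_cap


def flat_rate_table(rates_by_species=None):
    """Rate table with soil-invariant rows (null-equivalent by construction)."""
    if rates_by_species is None:
        rates_by_species = {sp: 1.05 for sp in ps.SPECIES}
    rates = pd.DataFrame(
        {soil: pd.Series(rates_by_species) for soil in ps.SOIL_TYPES}
    ).reindex(list(ps.SPECIES))
    null = pd.Series(rates_by_species).reindex(list(ps.SPECIES))
    return ps.RateTable(rates, null)


def make_table(rate_map):
    """RateTable from {(species, soil): rate}, default 1.0 elsewhere."""
    rates = pd.DataFrame(1.0, index=list(ps.SPECIES), columns=list(ps.SOIL_TYPES))
    for (sp, soil), r in rate_map.items():
        rates.at[sp, soil] = r
    null = pd.Series({sp: rates.at[sp, ps.SELF_SOIL[sp]] for sp in ps.SPECIES})
    return ps.RateTable(rates, null)


CAPS = ps.CarryingCapacities(0.42, 0.41)


def config(table, **kw):
    kw.setdefault("capacities", CAPS)
    return ps.SimulationConfig(rate_table=table, **kw)


class TestEffectiveRate:
    def test_single_soil_returns_cell_rate(self):
        table = make_table({("PSSP", "CEDI"): 1.2})
        state = ps.initial_state({"CEDI": 1.0})
        assert ps.effective_rate("PSSP", state, config(table)) == pytest.approx(1.2)

    def test_even_mix_of_opposed_rates_is_neutral(self):
        table = make_table({("PSSP", "PSSP"): 1.2, ("PSSP", "CEDI"): 0.8})
        state = ps.initial_state({"PSSP": 0.5, "CEDI": 0.5})
        assert ps.effective_rate("PSSP", state, config(table)) == pytest.approx(1.0)

    def test_weighted_sum_matches_dot_product(self, noise_free_rates):
        soil = {"PSSP": 0.25, "BRTE": 0.25, "CEDI": 0.30, "SILO": 0.20}
        state = ps.initial_state(soil)
        cfg = config(noise_free_rates)
        for sp in ps.SPECIES:
            expected = sum(
                soil.get(s, 0.0) * noise_free_rates.rates.at[sp, s]
                for s in ps.SOIL_TYPES
            )
            assert ps.effective_rate(sp, state, cfg) == pytest.approx(expected, rel=1e-12)

    def test_feedback_off_uses_null_rate(self, noise_free_rates):
        state = ps.initial_state({"CEDI": 1.0})
        cfg = config(noise_free_rates, feedback=False)
        for sp in ps.SPECIES:
            assert ps.effective_rate(sp, state, cfg) == pytest.approx(
                noise_free_rates.null_rates[sp], rel=1e-12
            )

    def test_unknown_species_rejected(self, noise_free_rates):
        state = ps.initial_state({"CEDI": 1.0})
        with pytest.raises(KeyError):
            ps.effective_rate("POBU", state, config(noise_free_rates))


class TestApplyCapacity:
    def test_identity_below_capacity(self):
        cover = {sp: 0.05 for sp in ps.SPECIES}
        assert ps.apply_capacity(cover, CAPS) == cover

    def test_proportional_rescale_to_group_k(self):
        cover = {"PSSP": 0.4, "FEID": 0.15, "KOCR": 0.05}
        capped = ps.apply_capacity(cover, CAPS)
        assert capped["PSSP"] == pytest.approx(0.28)
        assert capped["FEID"] == pytest.approx(0.105)
        assert capped["KOCR"] == pytest.approx(0.035)

    def test_groups_capped_independently(self):
        cover = {"PSSP": 0.84, "BRTE": 0.2}
        capped = ps.apply_capacity(cover, CAPS)
        assert capped["PSSP"] == pytest.approx(0.42)
        assert capped["BRTE"] == pytest.approx(0.2)

    @given(
        covers=st.lists(st.floats(0.0, 0.5), min_size=6, max_size=6),
        k=st.floats(0.05, 0.6),
    )
    def test_rescale_preserves_within_group_ratios(self, covers, k):
        cover = dict(zip(ps.SPECIES, covers))
        caps = ps.CarryingCapacities(k, k)
        capped = ps.apply_capacity(cover, caps)
        for group in (ps.NATIVE, ps.NON_NATIVE):
            total = sum(cover[sp] for sp in group)
            capped_total = sum(capped[sp] for sp in group)
            assert capped_total <= k + 1e-9
            if total > 0:
                scale = capped_total / total
                for sp in group:
                    assert capped[sp] == pytest.approx(cover[sp] * scale, rel=1e-9)

    def test_zero_total_unchanged(self):
        assert ps.apply_capacity({sp: 0.0 for sp in ps.SPECIES}, CAPS) == {
            sp: 0.0 for sp in ps.SPECIES
        }

    def test_pot_cap_rescales_everything(self):
        cover = np.array([0.2, 0.1, 0.1, 0.2, 0.2, 0.2])
        capped = _apply_pot_cap(cover, 0.5)
        assert capped.sum() == pytest.approx(0.5)
        assert np.allclose(capped / cover, 0.5 / cover.sum())


class TestUpdateSoils:
    def test_single_species_monopolises_its_soil(self, noise_free_rates):
        state = CommunityState.from_maps({"CEDI": 0.2}, {"PSSP": 1.0})
        soils = ps.update_soils(state, config(noise_free_rates))
        assert soils["CEDI"] == pytest.approx(1.0)
        assert sum(soils.values()) == pytest.approx(1.0)

    def test_normalisation_arithmetic(self, noise_free_rates):
        state = CommunityState.from_maps({"PSSP": 0.1, "CEDI": 0.3}, {"Mixed": 1.0})
        soils = ps.update_soils(state, config(noise_free_rates))
        assert soils["PSSP"] == pytest.approx(0.25)
        assert soils["CEDI"] == pytest.approx(0.75)

    def test_subordinate_natives_cultivate_native_soil(self, noise_free_rates):
        state = CommunityState.from_maps(
            {"FEID": 0.1, "KOCR": 0.1, "BRTE": 0.2}, {"Mixed": 1.0}
        )
        soils = ps.update_soils(state, config(noise_free_rates))
        assert soils["PSSP"] == pytest.approx(0.5)
        assert soils["BRTE"] == pytest.approx(0.5)
        assert soils["Mixed"] == 0.0

    def test_zero_cover_holds_previous_soils(self, noise_free_rates, caplog):
        state = CommunityState.from_maps({}, {"CEDI": 0.4, "PSSP": 0.6})
        with caplog.at_level("WARNING"):
            soils = ps.update_soils(state, config(noise_free_rates))
        assert soils == state.soil_map()
        assert "zero" in caplog.text


class TestSimulate:
    def test_unit_rates_are_a_fixed_point(self):
        table = flat_rate_table({sp: 1.0 for sp in ps.SPECIES})
        initial = ps.initial_state({"PSSP": 0.5, "CEDI": 0.5})
        traj = ps.simulate(initial, config(table, n_steps=20))
        assert np.allclose(traj.final.cover, initial.cover)

    def test_exponential_closed_form_on_single_soil(self):
        """Non-binding K: cover follows I * r^t exactly; season end hits F."""
        r = ps.step_rate(0.3, 0.004, 55)
        table = make_table({("BRTE", "BRTE"): r})
        cfg = config(
            table,
            capacities=ps.CarryingCapacities(0.99, 0.99),
            n_steps=55,
            pot_capacity=None,
        )
        state = CommunityState.from_maps({"BRTE": 0.004}, {"BRTE": 1.0})
        traj = ps.simulate(state, cfg)
        idx = ps.SPECIES.index("BRTE")
        for t in (1, 10, 33, 55):
            assert traj[t].cover[idx] == pytest.approx(0.004 * r**t, rel=1e-9)
        assert traj.final.cover[idx] == pytest.approx(0.3, rel=1e-9)

    def test_null_equivalence_bitwise_for_flat_tables(self):
        table = flat_rate_table(
            {sp: 1.0 + 0.01 * i for i, sp in enumerate(ps.SPECIES)}
        )
        initial = ps.initial_state({"PSSP": 0.3, "BRTE": 0.3, "CEDI": 0.4})
        a = ps.simulate(initial, config(table, n_steps=165, feedback=True))
        b = ps.simulate(initial, config(table, n_steps=165, feedback=False))
        for sa, sb in zip(a.states, b.states):
            assert np.array_equal(sa.cover, sb.cover)
            assert np.array_equal(sa.soil, sb.soil)

    def test_trajectory_length_and_reproducibility(self, noise_free_rates, noise_free_caps):
        cfg = ps.SimulationConfig(
            rate_table=noise_free_rates, capacities=noise_free_caps, n_steps=165
        )
        initial = ps.initial_state({"PSSP": 0.25, "BRTE": 0.27, "CEDI": 0.30, "SILO": 0.18})
        a = ps.simulate(initial, cfg)
        b = ps.simulate(initial, cfg)
        assert len(a) == 166
        for sa, sb in zip(a.states, b.states):
            assert np.array_equal(sa.cover, sb.cover)

    def test_monotone_dominance_with_shared_cap(self):
        """A species whose rate beats another's on every soil never falls behind it."""
        table = make_table(
            {("BRTE", s): 1.06 for s in ps.SOIL_TYPES}
            | {("CEDI", s): 1.03 for s in ps.SOIL_TYPES}
            | {("PSSP", s): 1.05 for s in ps.SOIL_TYPES}
        )
        caps = ps.CarryingCapacities(0.42, 0.42)
        cfg = config(table, capacities=caps, n_steps=165, pot_capacity=0.42)
        traj = ps.simulate(ps.initial_state({"PSSP": 0.5, "BRTE": 0.5}), cfg)
        ib, ic, ip = (ps.SPECIES.index(s) for s in ("BRTE", "CEDI", "PSSP"))
        for state in traj.states:
            assert state.cover[ib] >= state.cover[ic] - 1e-12
            assert state.cover[ib] >= state.cover[ip] - 1e-12

    @given(
        seed=st.integers(0, 10_000),
    )
    def test_invariants_on_random_configs(self, seed):
        """Soils sum to 1, covers stay non-negative, group totals respect K."""
        rng = np.random.default_rng(seed)
        rates = pd.DataFrame(
            rng.uniform(0.9, 1.15, size=(6, 5)),
            index=list(ps.SPECIES), columns=list(ps.SOIL_TYPES),
        )
        null = pd.Series({sp: rates.at[sp, ps.SELF_SOIL[sp]] for sp in ps.SPECIES})
        table = ps.RateTable(rates, null)
        caps = ps.CarryingCapacities(rng.uniform(0.1, 0.6), rng.uniform(0.1, 0.6))
        soil = rng.dirichlet(np.ones(5))
        cfg = ps.SimulationConfig(
            rate_table=table, capacities=caps, n_steps=40,
            soil_update_interval=int(rng.integers(1, 20)),
            pot_capacity=None if seed % 3 == 0 else "auto",
            feedback=bool(seed % 2),
        )
        initial = ps.initial_state(dict(zip(ps.SOIL_TYPES, soil)))
        traj = ps.simulate(initial, cfg)
        for state in traj.states:
            state.validate(caps)

    def test_damped_variant_stays_below_capacity(self, noise_free_rates):
        caps = ps.CarryingCapacities(0.42, 0.41)
        cfg = config(
            noise_free_rates, capacities=caps, n_steps=165, growth_form="damped",
            pot_capacity=None,
        )
        traj = ps.simulate(ps.initial_state({"PSSP": 0.5, "CEDI": 0.5}), cfg)
        for state in traj.states:
            assert state.group_total("native") <= 0.42 + 1e-9
            assert state.group_total("non-native") <= 0.41 + 1e-9

    def test_tidy_export_shape(self, noise_free_rates, noise_free_caps):
        cfg = ps.SimulationConfig(
            rate_table=noise_free_rates, capacities=noise_free_caps, n_steps=10
        )
        traj = ps.simulate(ps.initial_state({"PSSP": 1.0}), cfg)
        tidy = traj.to_tidy()
        assert set(tidy["kind"]) == {"cover", "soil"}
        assert len(tidy) == 11 * (6 + 5)
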