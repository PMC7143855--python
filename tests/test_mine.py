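"""Tests for the five-subsystem mining-area model and the quality assessment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from minesd.engine import SimConfig, simulate, validate_model
from minesd.mine import (
    SUBSYSTEM_STOCKS,
    SUBSYSTEMS,
    AllocationPolicy,
    MineModelConfig,
    MineParams,
    ZERO_POLICY,
    assemble_full_model,
    baseline_trajectory,
    build_air_subsystem,
    build_land_subsystem,
    build_solid_subsystem,
    build_subsystem,
    build_vegetation_subsystem,
    build_water_subsystem,
    quality_assessment,
    technical_factor,
)

from conftest import linear_closed_form


UNIFORM = AllocationPolicy(p_air=0.2, p_solid=0.2, p_water=0.2, p_green=0.2, p_land=0.2)


class TestTechnicalFactor:
    @pytest.mark.parametrize("p, e", [(0.4, 50), (0.0, 50), (0.2, 50), (1.0, 0.001)])
    def test_chained_form_cancels_to_proportion(self, p, e):
        assert technical_factor(p, e) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("e", [0.0, -1.0])
    def test_nonpositive_budget_rejected(self, e):
        with pytest.raises(ValueError):
            technical_factor(0.2, e)

    @settings(max_examples=200, derandomize=True)
    @given(p=st.floats(0, 1), e=st.floats(1e-6, 1e9))
    def test_cancellation_over_random_budgets(self, p, e):
        assert abs(technical_factor(p, e) - p) <= 1e-12


class TestAllocationPolicy:
    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValidationError, match="p_green"):
            AllocationPolicy(p_green=1.5)

    def test_over_budget_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            AllocationPolicy(p_air=0.5, p_solid=0.5, p_water=0.5)

    def test_tabulated_cases_fit_budget(self):
        AllocationPolicy(p_air=0.4, p_solid=0.15, p_water=0.15, p_green=0.15, p_land=0.15)


class TestMineParams:
    def test_land_area_alias_accepted(self):
        assert MineParams(**{"land_area": 500.0}).land_damage_init == 500.0

    def test_negative_constant_rejected(self):
        with pytest.raises(ValidationError, match="dust"):
            MineParams(dust=-1)

    def test_waste_gas_components_require_all_three(self):
        assert MineParams(no2=1.0, so2=2.0).waste_gas_components is None
        assert MineParams(no2=1, so2=2, co=3).waste_gas_components == (1, 2, 3)


class TestAirSubsystem:
    def test_production_rate_constant_4824(self, default_config, sim24):
        spec = build_air_subsystem(default_config, UNIFORM)
        traj = simulate(spec, sim24)
        assert np.allclose(traj.series["air_pollution_production"], 4824.0)

    def test_no_treatment_grows_linearly(self, default_config, sim24):
        traj = simulate(build_air_subsystem(default_config, ZERO_POLICY), sim24)
        assert np.allclose(traj.series["air_pollution"], 300.0 + 4824.0 * np.arange(25))

    def test_boosted_case_matches_closed_form(self, default_config, sim24):
        policy = AllocationPolicy(p_air=0.4)
        traj = simulate(build_air_subsystem(default_config, policy), sim24)
        assert traj.series["air_pollution"][-1] == pytest.approx(12059.944, abs=1e-3)

    def test_gas_components_replace_aggregate(self, sim24):
        cfg = MineModelConfig(params=MineParams(no2=1000.0, so2=400.0, co=114.0))
        traj = simulate(build_air_subsystem(cfg, UNIFORM), sim24)
        assert traj.series["waste_gas"][0] == pytest.approx(1514.0)
        assert np.allclose(traj.series["air_pollution_production"], 4824.0)


class TestSolidSubsystem:
    def test_production_9048(self, default_config, sim24):
        traj = simulate(build_solid_subsystem(default_config, UNIFORM), sim24)
        assert np.allclose(traj.series["solid_waste_production"], 9048.0)

    def test_full_removal_stock_equals_production(self, sim24):
        cfg = MineModelConfig()
        policy = AllocationPolicy(p_solid=1.0)
        traj = simulate(build_solid_subsystem(cfg, policy), sim24)
        assert np.allclose(traj.series["solid_waste_pollution"][1:], 9048.0)

    def test_literal_basis_accumulates_untreated_fraction(self, sim24):
        cfg = MineModelConfig(removal_basis="literal")
        policy = AllocationPolicy(p_solid=0.4)
        traj = simulate(build_solid_subsystem(cfg, policy), sim24)
        expected = 25.6 + 0.6 * 9048.0 * np.arange(25)
        np.testing.assert_allclose(traj.series["solid_waste_pollution"], expected, rtol=1e-12)


class TestWaterSubsystem:
    def test_production_15195(self, default_config, sim24):
        traj = simulate(build_water_subsystem(default_config, UNIFORM), sim24)
        assert np.allclose(traj.series["water_pollution_production"], 15195.0)

    def test_no_treatment_hand_arithmetic(self, default_config, sim24):
        traj = simulate(build_water_subsystem(default_config, ZERO_POLICY), sim24)
        assert traj.series["water_pollution"][-1] == pytest.approx(35.0 + 24 * 15195.0)

    def test_pure_decay_without_production(self, sim24):
        params = MineParams(coal_gangue=0, life_wastewater=0, mine_water=0, gangue_leaching=0)
        cfg = MineModelConfig(params=params)
        traj = simulate(build_water_subsystem(cfg, AllocationPolicy(p_water=0.15)), sim24)
        np.testing.assert_allclose(
            traj.series["water_pollution"], 35.0 * 0.85 ** np.arange(25), rtol=1e-12
        )


class TestVegetationSubsystem:
    def test_harmonized_production(self, default_config, sim24):
        traj = simulate(build_vegetation_subsystem(default_config, UNIFORM), sim24)
        assert np.allclose(traj.series["vegetation_destruction_production"], 4.1413)

    def test_raw_production_without_harmonization(self, sim24):
        cfg = MineModelConfig(unit_harmonization="off")
        traj = simulate(build_vegetation_subsystem(cfg, UNIFORM), sim24)
        assert np.allclose(traj.series["vegetation_destruction_production"], 41413.0)

    def test_greening_rate_from_intact_fraction(self, default_config, sim24):
        traj = simulate(build_vegetation_subsystem(default_config, ZERO_POLICY), sim24)
        assert traj.series["vegetation_greening_rate"][0] == pytest.approx(
            1.0 - 275.0 / 2645.2, abs=1e-4
        )

    def test_greening_rate_is_one_when_nothing_destroyed(self, sim24):
        cfg = MineModelConfig(
            params=MineParams(
                vegetation_destruction_init=0.0,
                construction_square=0, waste_rock_pile=0, open_pit=0, road=0,
            )
        )
        traj = simulate(build_vegetation_subsystem(cfg, ZERO_POLICY), sim24)
        assert np.allclose(traj.series["vegetation_greening_rate"], 1.0)


class TestLandSubsystem:
    def test_harmonized_production(self, default_config, sim24):
        traj = simulate(build_land_subsystem(default_config, UNIFORM), sim24)
        assert np.allclose(traj.series["land_damage_production"], 1.32)

    def test_no_treatment_hand_arithmetic(self, default_config, sim24):
        traj = simulate(build_land_subsystem(default_config, ZERO_POLICY), sim24)
        assert traj.series["land_damage_area"][-1] == pytest.approx(481.68)

    def test_higher_proportion_dominates_pathwise(self, default_config, sim24):
        lo = simulate(build_land_subsystem(default_config, AllocationPolicy(p_land=0.15)), sim24)
        hi = simulate(build_land_subsystem(default_config, AllocationPolicy(p_land=0.4)), sim24)
        assert np.all(
            hi.series["land_damage_area"][1:] < lo.series["land_damage_area"][1:]
        )


class TestAssembledModel:
    def test_five_stocks_and_valid(self, default_config):
        spec = assemble_full_model(default_config, UNIFORM)
        assert len(spec.stocks) == 5
        assert validate_model(spec) == []
        assert set(spec.stock_names) == set(SUBSYSTEM_STOCKS.values())

    def test_fragments_reproduce_assembled_series(self, default_config, sim24):
        """Subsystem independence: the full model equals the isolated fragments."""
        policy = AllocationPolicy(p_air=0.4, p_solid=0.15, p_water=0.15, p_green=0.15, p_land=0.15)
        full = simulate(assemble_full_model(default_config, policy), sim24)
        for sub, stock in SUBSYSTEM_STOCKS.items():
            alone = simulate(build_subsystem(sub, default_config, policy), sim24)
            assert np.array_equal(full.series[stock], alone.series[stock])

    def test_cross_independence_bit_identical(self, default_config, sim24):
        a = simulate(assemble_full_model(default_config, UNIFORM), sim24)
        b = simulate(
            assemble_full_model(default_config, UNIFORM.replace(p_air=0.05)), sim24
        )
        for stock in SUBSYSTEM_STOCKS.values():
            if stock == "air_pollution":
                assert not np.array_equal(a.series[stock], b.series[stock])
            else:
                assert np.array_equal(a.series[stock], b.series[stock])

    def test_conflicting_shared_constant_is_a_collision(self, default_config):
        from minesd.engine import ConstantDef, ModelSpec

        frag = build_air_subsystem(default_config, UNIFORM)
        clash = ModelSpec(constants=[ConstantDef("environmental_investment", 99.0)])
        with pytest.raises(ValueError, match="collision"):
            ModelSpec.merge(frag, clash)


class TestQualityAssessment:
    def test_zero_policy_scores_zero(self, default_config, sim24):
        base = baseline_trajectory(default_config, sim24)
        q = quality_assessment(base, base)
        assert np.all(q.overall == 0.0)
        for series in q.per_subsystem.values():
            assert np.all(series == 0.0)

    def test_overall_is_mean_of_subsystems(self, default_config, sim24):
        base = baseline_trajectory(default_config, sim24)
        treated = simulate(assemble_full_model(default_config, UNIFORM), sim24)
        q = quality_assessment(treated, base)
        stacked = np.stack([q.per_subsystem[s] for s in SUBSYSTEMS])
        np.testing.assert_allclose(q.overall, stacked.mean(axis=0), rtol=1e-12)

    def test_air_quality_value_at_horizon(self, default_config, sim24):
        base = baseline_trajectory(default_config, sim24)
        policy = AllocationPolicy(p_air=0.4)
        treated = simulate(assemble_full_model(default_config, policy), sim24)
        q = quality_assessment(treated, base)
        # 1 - 12059.944 / (300 + 24 * 4824)
        assert q.per_subsystem["air"][-1] == pytest.approx(0.8961, abs=1e-4)

    def test_mismatched_grids_rejected(self, default_config, sim24):
        base = baseline_trajectory(default_config, sim24)
        short = baseline_trajectory(default_config, SimConfig(final_time=12))
        with pytest.raises(ValueError, match="grid"):
            quality_assessment(short, base)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        props=st.lists(st.floats(0, 0.2), min_size=5, max_size=5),
    )
    def test_quality_bounded_for_any_feasible_policy(self, props):
        policy = AllocationPolicy(
            p_air=props[0], p_solid=props[1], p_water=props[2],
            p_green=props[3], p_land=props[4],
        )
        cfg = MineModelConfig()
        sim = SimConfig(final_time=12)
        base = baseline_trajectory(cfg, sim)
        treated = simulate(assemble_full_model(cfg, policy), sim)
        q = quality_assessment(treated, base)
        assert np.all(q.overall >= 0.0) and np.all(q.overall <= 1.0)
        for series in q.per_subsystem.values():
            assert np.all(series >= 0.0) and np.all(series <= 1.0)
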