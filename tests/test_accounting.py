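"""Per-hectare activity accounting: embedded machinery burdens, soil N2O,
operation hours/fuel, pesticide programmes and the GM/NE/GHG identities."""

from types import SimpleNamespace

import pytest

import tillageopt as t
from tillageopt.accounting import (
    Activity,
    activity_coefficients,
    enumerate_activities,
    machinery_hourly_embedded,
    operation_hours_and_fuel,
    pesticide_program_cost,
    soil_n2o_co2e,
)
from tillageopt.domain import EmissionFactors, EnergyFactors


class TestEmbeddedMachinery:
    @pytest.mark.parametrize(
        "machine_id, mj_h",
        [
            ("one_pass_cultivator", 56.35),
            ("medium_disc", 13.19),
            ("spring_tine", 26.83),
        ],
    )
    def test_hourly_energy_from_weight(self, calib, machine_id, mj_h):
        got, _ = machinery_hourly_embedded(
            calib.machines[machine_id], calib.energy_factors, calib.emission_factors
        )
        assert round(got, 2) == mj_h

    def test_rate_times_lifespan_equals_weight_times_factor(self, calib):
        for m in calib.machines.values():
            mj_h, kg_h = machinery_hourly_embedded(
                m, calib.energy_factors, calib.emission_factors
            )
            assert mj_h * m.lifespan_h == pytest.approx(
                m.weight_kg * calib.energy_factors.steel_mj_kg, abs=1e-9
            )
            assert kg_h * m.lifespan_h == pytest.approx(
                m.weight_kg * calib.emission_factors.steel_kgco2_kg, abs=1e-9
            )

    def test_weightless_machine_carries_no_burden(self, calib):
        ghost = SimpleNamespace(weight_kg=0.0, lifespan_h=3000.0)
        assert machinery_hourly_embedded(
            ghost, calib.energy_factors, calib.emission_factors
        ) == (0.0, 0.0)

    def test_nonpositive_lifespan_rejected(self, calib):
        ghost = SimpleNamespace(weight_kg=100.0, lifespan_h=0.0)
        with pytest.raises(ValueError):
            machinery_hourly_embedded(ghost, calib.energy_factors, calib.emission_factors)


class TestSoilN2O:
    def test_background_only(self):
        f = EmissionFactors()
        assert round(soil_n2o_co2e(0.0, f), 1) == 655.6

    def test_hundred_kg_applied(self):
        f = EmissionFactors()
        assert round(soil_n2o_co2e(100.0, f), 1) == 1404.9

    def test_strictly_increasing_in_applied_n(self):
        f = EmissionFactors()
        vals = [soil_n2o_co2e(n, f) for n in (0, 50, 100, 200, 400)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            soil_n2o_co2e(-1.0, EmissionFactors())


class TestOperationHours:
    def test_ct_wheat_is_247_minutes(self, calib):
        hours, _ = operation_hours_and_fuel(
            calib.tillage_systems["CT"], "WW1", calib
        )
        assert sum(hours.values()) * 60 == pytest.approx(70 + 2 * 67 + 43)

    @pytest.mark.parametrize("crop", ["WW1", "WB", "SB", "WOSR", "WFB"])
    def test_zt_is_drill_only(self, calib, crop):
        hours, _ = operation_hours_and_fuel(calib.tillage_systems["ZT"], crop, calib)
        assert sum(hours.values()) * 60 == pytest.approx(43)

    def test_drt_beans_single_pass(self, calib):
        hours, _ = operation_hours_and_fuel(calib.tillage_systems["DRT"], "WFB", calib)
        assert sum(hours.values()) * 60 == pytest.approx(24 + 43)

    def test_broadcast_wosr_has_no_drill_pass(self, calib):
        rt_hours, _ = operation_hours_and_fuel(
            calib.tillage_systems["SRT1"], "WOSR", calib
        )
        assert sum(rt_hours.values()) * 60 == pytest.approx(2 * 42)  # no drill
        zt_hours, _ = operation_hours_and_fuel(
            calib.tillage_systems["ZT"], "WOSR", calib
        )
        assert sum(zt_hours.values()) * 60 == pytest.approx(43)  # drill required

    def test_unknown_crop_rejected(self, calib):
        with pytest.raises(KeyError):
            operation_hours_and_fuel(calib.tillage_systems["CT"], "maize", calib)

    def test_fuel_follows_tractor_rates(self, calib):
        _, fuel = operation_hours_and_fuel(calib.tillage_systems["ZT"], "WW1", calib)
        mt = calib.machines["medium_tractor"].fuel_l_h
        assert fuel == pytest.approx(43 / 60 * mt)


class TestPesticides:
    def test_first_wheat_programme_2014(self, calib):
        cost = pesticide_program_cost(calib.crops["WW1"], calib.prices("2014"))
        assert cost == pytest.approx(77.93 + 44.04 + 23.50 + 4.96 + 14.81)

    def test_osr_programme_2011(self, calib):
        cost = pesticide_program_cost(calib.crops["WOSR"], calib.prices("2011"))
        assert cost == pytest.approx(29.14 + 89.43 + 12.87 + 20.66)

    def test_later_wheats_use_other_seed_treatment_line(self, calib):
        p = calib.prices("2011")
        ww1 = pesticide_program_cost(calib.crops["WW1"], p)
        ww2 = pesticide_program_cost(calib.crops["WW2"], p)
        assert ww2 - ww1 == pytest.approx(16.09 - 14.19)

    def test_empty_programme_costs_nothing(self, calib):
        bare = calib.crops["WFB"].model_copy(update={"pesticide_program": []})
        assert pesticide_program_cost(bare, calib.prices("2011")) == 0.0


class TestActivityIdentities:
    @pytest.mark.parametrize("tillage_id", ["CT", "ZT"])
    def test_accounting_identities_hold_exactly(self, calib, tillage_id):
        ts = calib.tillage_systems[tillage_id]
        for act in enumerate_activities(calib):
            c = activity_coefficients(act, ts, calib)
            ne_check = sum(c.energy_output_components.values()) - sum(
                c.energy_input_components.values()
            )
            assert c.ne_mj == pytest.approx(ne_check, abs=1e-9)
            assert c.ghg_kg == pytest.approx(sum(c.ghg_components.values()), abs=1e-9)
            gm_check = sum(c.revenue_components.values()) - sum(
                c.cost_components.values()
            )
            assert c.gm == pytest.approx(gm_check, abs=1e-9)
            assert all(h >= 0 for h in c.hours.values())

    def test_gm_is_affine_in_yield_multiplier(self, calib):
        """Three-point collinearity: grain drying is the only
        yield-proportional cost, so GM is a straight line in the uniform
        yield multiplier — the mechanism behind the linear penalty plots."""
        ts = calib.tillage_systems["ZT"]
        act = Activity("WW1", "baled", 0.75)
        g = [
            activity_coefficients(act, ts, calib, yield_multiplier=m).gm
            for m in (0.6, 0.8, 1.0)
        ]
        assert g[2] - g[1] == pytest.approx(g[1] - g[0], rel=1e-12)
        assert g[2] > g[0]  # positive slope: revenue exceeds drying cost

    def test_zero_yield_leaves_only_costs(self, calib):
        ts = calib.tillage_systems["ZT"]
        act = Activity("WW1", "incorporated", 1.0)
        c = activity_coefficients(act, ts, calib, yield_multiplier=0.0)
        assert c.gm == pytest.approx(-sum(c.cost_components.values()))
        assert c.output_t == 0.0

    def test_grain_price_scales_only_grain_revenue(self, calib):
        doubled = calib.model_copy(deep=True)
        doubled.price_sets["2011"].grain_prices["WW"] *= 2
        ts = calib.tillage_systems["CT"]
        act = Activity("WW1", "baled", 0.75)
        base = activity_coefficients(act, ts, calib)
        up = activity_coefficients(act, doubled.tillage_systems["CT"], doubled)
        assert up.revenue_components["grain"] == pytest.approx(
            2 * base.revenue_components["grain"]
        )
        assert up.cost_components == base.cost_components
        assert up.revenue_components["straw"] == base.revenue_components["straw"]

    def test_missing_price_names_the_price(self, calib):
        broken = calib.model_copy(deep=True)
        del broken.price_sets["2011"].grain_prices["WOSR"]
        with pytest.raises(KeyError, match="WOSR"):
            activity_coefficients(
                Activity("WOSR", None, 1.0), broken.tillage_systems["ZT"], broken
            )
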