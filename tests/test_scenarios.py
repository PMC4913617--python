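"""Scenario engine: yield-penalty thresholds, land compensation, weed
control, spring-barley selection and the scenario matrix."""

import numpy as np
import pandas as pd
import pytest

import tillageopt as t
from tillageopt.scenarios import metric_value, pairwise_deltas


def solve_penalised(calib, tillage_id, p, objective="max_GM"):
    return t.solve(
        t.build_program(calib, tillage_id, objective, yield_multiplier=1.0 - p)
    )


class TestYieldThreshold:
    def test_ct_against_itself_breaks_even_at_zero(self, calib):
        res = t.yield_threshold("CT", "GM", calib)
        assert res.p_star == 0.0

    def test_closed_form_on_pinned_mix(self, single_crop_calib):
        """With one crop the mix cannot shift, GM(p) = A - B p exactly, so
        the breakeven penalty of direct drilling against ploughing has a
        closed form the bisection must reproduce."""
        c = single_crop_calib
        zt0 = solve_penalised(c, "ZT", 0.0)
        zt_half = solve_penalised(c, "ZT", 0.5)
        ct0 = solve_penalised(c, "CT", 0.0)
        B = (zt0.gm - zt_half.gm) / 0.5
        expected = (zt0.gm - ct0.gm) / B
        res = t.yield_threshold("ZT", "GM", c, tol=1e-9)
        assert res.p_star == pytest.approx(expected, abs=1e-6)

    def test_bisection_agrees_with_grid_scan(self, calib):
        """The bisection threshold matches a 0.1%-step grid scan of the
        re-optimised GM curve within 0.001."""
        res = t.yield_threshold("ZT", "GM", calib, tol=1e-7)
        target = res.baseline_value
        grid = np.arange(0.0, 0.15 + 1e-12, 0.001)
        vals = [solve_penalised(calib, "ZT", p).gm for p in grid]
        crossing = next(p for p, v in zip(grid, vals) if v <= target)
        assert res.p_star == pytest.approx(crossing, abs=0.001)

    def test_threshold_satisfies_its_equation(self, calib):
        for metric in ("GM", "NE"):
            res = t.yield_threshold("ZT", metric, calib, tol=1e-4)
            assert res.p_star is not None and 0 < res.p_star < 1
            sol = t.solve(
                t.build_program(
                    calib, "ZT",
                    "max_NE" if metric == "NE" else "max_GM",
                    yield_multiplier=1.0 - res.p_star,
                )
            )
            base0 = solve_penalised(calib, "ZT", 0.0)
            got = metric_value(metric, sol, baseline=base0)
            assert got == pytest.approx(res.baseline_value,
                                        rel=1e-4, abs=1e-4 * abs(res.baseline_value))

    def test_per_tonne_threshold_exists_when_mix_is_pinned(self, single_crop_calib):
        res = t.yield_threshold("ZT", "GHG_per_t_output", single_crop_calib)
        assert res.p_star is not None and 0 < res.p_star < 1

    def test_gm_curve_is_convex_and_nonincreasing(self, calib):
        """The optimised GM is a maximum of affine functions of the
        penalty: piecewise linear, convex, nonincreasing."""
        grid = np.linspace(0.0, 0.3, 7)
        vals = [solve_penalised(calib, "ZT", p).gm for p in grid]
        assert all(b <= a + 1e-6 for a, b in zip(vals, vals[1:]))
        for i in range(1, len(grid) - 1):
            mid = 0.5 * (vals[i - 1] + vals[i + 1])
            assert vals[i] <= mid + 1e-6 * abs(mid)


class TestLandCompensation:
    def test_pure_penalty_gives_algebraic_fraction(self, single_crop_calib):
        p = 0.142
        base = solve_penalised(single_crop_calib, "ZT", 0.0)
        pen = solve_penalised(single_crop_calib, "ZT", p)
        comp = t.land_compensation(pen, base, penalty=p)
        assert comp.extra_land_fraction_t == pytest.approx(1 / (1 - p) - 1, rel=1e-9)
        assert comp.extra_land_fraction_t == pytest.approx(0.1655, abs=5e-4)
        assert comp.extra_land_fraction_kcal == pytest.approx(
            comp.extra_land_fraction_t, rel=1e-9
        )

    def test_zero_penalty_needs_no_land(self, calib, gm_solutions):
        comp = t.land_compensation(gm_solutions["ZT"], gm_solutions["ZT"])
        assert comp.extra_land_fraction_t == pytest.approx(0.0, abs=1e-12)

    def test_mix_shift_to_lower_yielders_needs_more_land(self):
        """Constructed two-crop case: the baseline grows an 8 t/ha crop,
        the penalised farm swaps to a 6 t/ha crop under a 20% penalty, so
        the land fraction strictly exceeds the pure-penalty bound."""

        def plan(output_t):
            return t.FarmSolution(
                objective="max_GM", tillage_id="ZT", price_year="2011",
                areas={}, species_areas={}, gm=0.0, ne_gj=0.0, ghg_kg=1000.0,
                fuel_l=0.0, contractor_fees=0.0, own_hours={},
                contractor_hours={}, output_t=output_t,
                output_kcal=output_t * 3.3e6, objective_value=0.0,
            )

        p = 0.2
        base = plan(400 * 8.0)
        pen = plan(400 * 6.0 * (1 - p))
        comp = t.land_compensation(pen, base, penalty=p)
        assert comp.extra_land_fraction_t > 1 / (1 - p) - 1
        assert comp.total_ghg_with_extra_land > pen.ghg_kg

    def test_zero_output_rejected(self, calib, gm_solutions):
        dead = solve_penalised(calib, "ZT", 1.0)
        with pytest.raises(ValueError):
            t.land_compensation(dead, gm_solutions["ZT"])


class TestWeedControl:
    def test_no_addon_is_the_baseline(self, calib, gm_solutions):
        sol = t.solve(t.build_program(calib, "ZT", "max_GM", herbicide_addon=0.0))
        assert sol.gm == pytest.approx(gm_solutions["ZT"].gm)

    def test_addon_scales_with_farm_area_when_mix_holds(self, single_crop_calib):
        base = t.solve(t.build_program(single_crop_calib, "ZT", "max_GM"))
        dosed = t.solve(
            t.build_program(single_crop_calib, "ZT", "max_GM", herbicide_addon=42.5)
        )
        assert base.gm - dosed.gm == pytest.approx(42.5 * 400, rel=1e-9)

    def test_extreme_blackgrass_cost_keeps_zt_ahead_of_ct(self, calib, gm_solutions):
        sol, report = t.weed_control_scenario("ZT", calib, extreme=True)
        assert sol.gm > gm_solutions["CT"].gm
        assert report.other_costs == pytest.approx(4.81 * 400)


@pytest.fixture(scope="module")
def sweep(calib):
    return t.sb_selection_sweep(
        calib, "ZT", penalty_grid=[0.0, 0.05, 0.1, 0.14, 0.18, 0.2, 0.22, 0.25]
    )


class TestSpringBarleySweep:
    def test_not_selected_without_a_penalty(self, sweep):
        assert sweep.iloc[0]["sb_area_ha"] == pytest.approx(0.0, abs=1e-6)

    def test_area_nondecreasing_in_penalty(self, sweep):
        areas = sweep["sb_area_ha"].to_numpy()
        assert all(b >= a - 1e-6 for a, b in zip(areas, areas[1:]))

    def test_entry_only_under_large_penalties(self, sweep):
        assert sweep.attrs["entry_threshold"] is not None
        assert sweep.attrs["entry_threshold"] > 0.15
        assert sweep.attrs["threshold_100ha"] is not None

    def test_four_crops_at_twenty_percent(self, calib):
        ym = {cid: 0.8 for cid in calib.crops if cid != "SB"}
        sol = t.solve(t.build_program(calib, "ZT", "max_GM", yield_multiplier=ym))
        for sp in ("WW", "WB", "WOSR", "SB"):
            assert sol.species_areas.get(sp, 0.0) > 1.0


class TestScenarioMatrix:
    def test_empty_tillage_list_gives_empty_report(self, calib):
        report = t.scenario_matrix(calib, tillage_ids=[])
        assert report.solution_tables == {} and report.failures == []

    def test_matrix_covers_all_combinations(self, calib):
        report = t.scenario_matrix(
            calib, tillage_ids=["CT", "ZT"], objectives=["max_GM"]
        )
        assert set(report.solution_tables) == {"2011_base_max_GM"}
        assert list(report.solution_tables["2011_base_max_GM"].columns) == ["CT", "ZT"]
        assert report.failures == []
        assert "CT->ZT" in report.deltas["2011_base_max_GM"].columns

    def test_delta_reporting_on_published_metric_tables(self):
        """Feeding the published farm totals through the delta reporter
        reproduces the headline comparisons: a 25% GM premium and a 58%
        fuel cut for direct drilling, and a +256 GBP/ha net margin gap."""
        metrics = pd.DataFrame(
            {
                "CT": [285782.0, 91951.0, 432.0],
                "ZT": [357717.0, 38661.0, 688.0],
            },
            index=["gross_margin_gbp", "fuel_l", "nm_per_ha"],
        )
        deltas = pairwise_deltas(metrics)["CT->ZT"]
        assert deltas["gross_margin_gbp_pct"] == 25
        assert deltas["fuel_l_pct"] == -58
        assert deltas["nm_per_ha_diff"] == 256

    def test_report_writer_round_trips(self, calib, tmp_path):
        report = t.scenario_matrix(calib, tillage_ids=["CT", "ZT"],
                                   objectives=["max_GM"])
        report.write(tmp_path)
        written = pd.read_csv(tmp_path / "solutions_2011_base_max_GM.csv", index_col=0)
        assert written.loc["gross_margin_gbp", "ZT"] == pytest.approx(
            report.solution_tables["2011_base_max_GM"].loc["gross_margin_gbp", "ZT"]
        )
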