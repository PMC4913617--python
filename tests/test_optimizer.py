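"""The farm LP: rotation logic, resource/contractor balances, Greening,
and equivalence with an exhaustive grid-search oracle on small farms."""

import numpy as np
import pytest

import tillageopt as t
from tillageopt.accounting import activity_coefficients, enumerate_activities
from tillageopt.optimizer import InfeasibleProgramError

from conftest import make_toy


def best_gm_per_crop(calib, tillage_id="ZT"):
    ts = calib.tillage_systems[tillage_id]
    best = {}
    for act in enumerate_activities(calib):
        gm = activity_coefficients(act, ts, calib).gm
        if gm > best.get(act.crop_id, -np.inf):
            best[act.crop_id] = gm
    return best


class TestToyFarms:
    def test_dominant_activity_takes_all_land(self, single_crop_calib):
        sol = t.solve(t.build_program(single_crop_calib, "ZT", "max_GM"))
        best = best_gm_per_crop(single_crop_calib)
        assert sol.total_area == pytest.approx(400.0, abs=1e-6)
        assert len(sol.areas) == 1
        assert sol.gm == pytest.approx(400.0 * best["WWc"], rel=1e-9)

    def test_alternating_rotation_forces_even_split(self, pair_calib):
        """Wheat only after a break, rape only after a cereal: steady state
        pins each to half the farm; the optimum equals the hand sum."""
        sol = t.solve(t.build_program(pair_calib, "ZT", "max_GM"))
        assert sol.species_areas["WW"] == pytest.approx(200.0, abs=1e-6)
        assert sol.species_areas["WOSR"] == pytest.approx(200.0, abs=1e-6)
        best = best_gm_per_crop(pair_calib)
        assert sol.gm == pytest.approx(200 * (best["WW1"] + best["WOSR"]), rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_lp_matches_grid_search_oracle(self, calib, seed):
        """On a wheat/barley/rape farm the LP optimum equals brute-force
        enumeration over every rotation-feasible 1-ha mix within 0.5%.

        Rotation feasibility in this reduced network has a closed form:
        first wheat cannot exceed the break area (its only predecessor)
        and the break area cannot exceed first wheat + barley (its only
        successors' capacity to precede it).
        """
        toy = make_toy(t.random_calibration(seed), ("WW1", "WB", "WOSR"))
        g = best_gm_per_crop(toy)
        w1, osr = np.meshgrid(np.arange(401.0), np.arange(401.0), indexing="ij")
        wb = 400.0 - w1 - osr
        feasible = (wb >= 0) & (w1 <= osr) & (osr <= w1 + wb)
        obj = g["WW1"] * w1 + g["WB"] * wb + g["WOSR"] * osr
        brute = obj[feasible].max()
        sol = t.solve(t.build_program(toy, "ZT", "max_GM"))
        assert sol.gm == pytest.approx(brute, rel=5e-3)
        assert sol.gm >= brute - 1e-6  # LP is on a finer grid than 1 ha

    def test_unknown_objective_rejected(self, calib):
        with pytest.raises(ValueError, match="objective"):
            t.build_program(calib, "CT", "max_profit")


class TestFarmSolutions:
    def test_land_conservation_and_nonnegativity(self, gm_solutions):
        for sol in gm_solutions.values():
            assert sol.total_area == pytest.approx(400.0, abs=1e-6)
            assert all(a >= 0 for a in sol.areas.values())
            assert all(h >= -1e-9 for h in sol.own_hours.values())

    def test_metrics_recomputable_from_areas(self, calib, gm_solutions):
        """GM/NE/GHG cross-reporting: areas x the coefficient table must
        reproduce the reported farm totals (GM net of hourly contracting)."""
        for tid, sol in gm_solutions.items():
            table = t.activity_table(calib, tid).set_index("activity")
            gm = ne = ghg = fuel = 0.0
            for act_id, area in sol.areas.items():
                row = table.loc[act_id]
                gm += area * row["gm_gbp_ha"]
                ne += area * row["ne_mj_ha"]
                ghg += area * row["ghg_kg_ha"]
                fuel += area * row["fuel_l_ha"]
            hourly_fees = sol.contractor_fees - sum(
                area * table.loc[a]["cost_baling_contract"]
                for a, area in sol.areas.items()
            )
            assert sol.gm == pytest.approx(gm - hourly_fees, rel=1e-6)
            assert sol.ne_gj == pytest.approx(ne / 1000.0, rel=1e-6)
            assert sol.ghg_kg == pytest.approx(ghg, rel=1e-6)
            assert sol.fuel_l == pytest.approx(fuel, rel=1e-6)

    def test_deterministic_resolve(self, calib):
        a = t.solve(t.build_program(calib, "CT", "max_GM"))
        b = t.solve(t.build_program(calib, "CT", "max_GM"))
        assert a.areas == b.areas
        assert a.gm == b.gm

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_fewer_passes_never_reduce_optimised_gm(self, seed):
        """A tillage system whose pass counts are component-wise <= another's
        achieves at least the same optimised GM (costs and resource use only
        fall): direct drilling dominates both shallow-tillage systems."""
        calib = t.random_calibration(seed)
        zt = t.solve(t.build_program(calib, "ZT", "max_GM")).gm
        for shallower in ("SRT1", "SRT2"):
            assert zt >= t.solve(t.build_program(calib, shallower, "max_GM")).gm - 1e-6


class TestGreening:
    def test_two_species_farm_is_infeasible(self, pair_calib):
        with pytest.raises(InfeasibleProgramError, match="greening"):
            t.solve(t.build_program(pair_calib, "ZT", "max_GM", greening=True))

    def test_pairwise_caps_force_three_species(self, calib):
        for tid in ("CT", "ZT"):
            for obj in ("max_GM", "max_NE", "min_GHG"):
                sol = t.solve(t.build_program(calib, tid, obj, greening=True))
                areas = sorted(sol.species_areas.values(), reverse=True)
                assert len(areas) >= 3
                assert areas[0] + areas[1] <= 0.95 * 400 + 1e-6
                assert areas[2] >= 400 - 0.95 * 400 - 1e-6  # third-largest >= 20 ha

    def test_example_mix_is_feasible_under_caps(self):
        # a 200/180/20 species split satisfies every pairwise 95% cap
        areas = [200.0, 180.0, 20.0]
        assert all(
            a + b <= 380.0
            for i, a in enumerate(areas)
            for b in areas[i + 1 :]
        )
        assert 200.0 + 200.0 > 380.0  # a two-species farm cannot comply

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_greening_never_improves_the_objective(self, seed):
        calib = t.random_calibration(seed)
        for obj, sense in (("max_GM", 1), ("max_NE", 1), ("min_GHG", -1)):
            base = t.solve(t.build_program(calib, "ZT", obj)).objective_value
            capped = t.solve(
                t.build_program(calib, "ZT", obj, greening=True)
            ).objective_value
            assert sense * capped <= sense * base + 1e-6 * max(1.0, abs(base))


class TestContracting:
    def test_contracted_hours_cover_capacity_shortfall(self, calib, gm_solutions):
        """Wherever required hours exceed own capacity the gap is bought
        in; own hours never exceed the period capacity."""
        res = calib.resources
        for sol in gm_solutions.values():
            for (cls, pid), own in sol.own_hours.items():
                cap = res.period(pid).machine_h.get(cls.value, 0.0)
                assert own <= cap + 1e-6
        # conventional tillage cannot be worked with farm labour alone
        assert gm_solutions["CT"].contractor_fees > 0
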