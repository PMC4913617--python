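"""Scenario drivers built on the farm programme.

* baseline tillage comparison and net-margin reporting across systems;
* yield-penalty threshold search: bisection on a uniform yield penalty,
  re-optimising the LP at every step, until the chosen metric of the
  reduced-tillage system equals the conventional-tillage baseline;
* land/calorie compensation accounting for penalised systems;
* weed-control (black-grass herbicide) add-on runs;
* spring-barley selection sweep (stale-seedbed weed control);
* a scenario matrix over price years, tillage systems, objectives and
  Greening flags with tabular writers and pairwise delta reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .domain import Calibration
from .finance import NetMarginReport, net_margin, size_complement
from .optimizer import FarmSolution, build_program, solve

THRESHOLD_METRICS = ("GM", "NE", "GHG_per_t_output", "total_GHG_constant_production")

#: biennial black-grass herbicide programme, GBP/ha per application year
BLACKGRASS_COST = 85.0
#: machinery+fuel+labour cost of the extra spraying pass, GBP/ha/yr
EXTRA_SPRAY_COST = 4.81


@dataclass
class ThresholdResult:
    tillage_id: str
    metric: str
    p_star: float | None  # penalty fraction, None if no crossing in [0, 1]
    baseline_value: float  # conventional-tillage metric at zero penalty
    value_at_star: float | None
    solution_at_star: FarmSolution | None


@dataclass
class CompensationResult:
    penalty: float
    extra_land_fraction_t: float
    extra_land_fraction_kcal: float
    total_ghg_with_extra_land: float  # kg CO2-eq, farm + compensating land


def _solve_at(
    calib: Calibration,
    tillage_id: str,
    objective: str,
    price_year: str | int,
    penalty: float,
    greening: bool = False,
) -> FarmSolution:
    return solve(
        build_program(
            calib,
            tillage_id,
            objective,
            price_year,
            greening=greening,
            yield_multiplier=1.0 - penalty,
        )
    )


def metric_value(
    metric: str,
    solution: FarmSolution,
    baseline: FarmSolution | None = None,
) -> float:
    """Extract a threshold metric from a solved plan.

    ``total_GHG_constant_production`` needs the zero-penalty baseline to
    scale production up to equal calorie output via compensating land.
    """
    if metric == "GM":
        return solution.gm
    if metric == "NE":
        return solution.ne_gj
    if metric == "GHG_per_t_output":
        if solution.output_t <= 0:
            raise ValueError("zero output: GHG per tonne undefined")
        return solution.ghg_kg / solution.output_t
    if metric == "total_GHG_constant_production":
        if baseline is None:
            raise ValueError("baseline solution required for this metric")
        comp = land_compensation(solution, baseline)
        return comp.total_ghg_with_extra_land
    raise ValueError(f"unknown metric {metric!r}")


def yield_threshold(
    tillage_id: str,
    metric: str,
    calib: Calibration,
    price_year: str | int = "2011",
    tol: float = 1e-3,
    max_iter: int = 60,
) -> ThresholdResult:
    """Breakeven yield penalty of a tillage system against the CT baseline.

    Bisection on the penalty fraction p in [0, 1], re-optimising the farm
    programme at each step, until the metric at p matches the
    conventional-tillage zero-penalty value within ``tol`` (relative to
    the baseline magnitude).  GM- and GHG-based metrics re-optimise the
    profit objective (the farmer's mix); NE re-optimises net energy.
    """
    if metric not in THRESHOLD_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {THRESHOLD_METRICS}")
    objective = "max_NE" if metric == "NE" else "max_GM"
    ct0 = _solve_at(calib, "CT", objective, price_year, 0.0)
    target = metric_value(metric, ct0, baseline=ct0)
    scale = max(1.0, abs(target))

    base0 = _solve_at(calib, tillage_id, objective, price_year, 0.0)

    def h(p: float) -> float:
        sol = _solve_at(calib, tillage_id, objective, price_year, p)
        try:
            return metric_value(metric, sol, baseline=base0) - target, sol
        except ValueError:
            # zero output at a total penalty: per-output metrics diverge
            return float("inf"), sol

    h0, s0 = h(0.0)
    if abs(h0) <= tol * scale:
        return ThresholdResult(tillage_id, metric, 0.0, target, target + h0, s0)
    h1, s1 = h(1.0)
    if (h0 > 0) == (h1 > 0):
        return ThresholdResult(tillage_id, metric, None, target, None, None)

    lo, hi = 0.0, 1.0
    h_lo = h0
    mid, h_mid, s_mid = 0.5, h1, s1
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        h_mid, s_mid = h(mid)
        if abs(h_mid) <= tol * scale:
            break
        if (h_mid > 0) == (h_lo > 0):
            lo, h_lo = mid, h_mid
        else:
            hi = mid
    return ThresholdResult(tillage_id, metric, mid, target, target + h_mid, s_mid)


def land_compensation(
    solution_at_p: FarmSolution,
    baseline_solution: FarmSolution,
    penalty: float = 0.0,
) -> CompensationResult:
    """Extra land needed to restore the baseline farm output.

    Uses the penalised solution's own crop mix for the compensating land,
    so a mix shift toward lower-yielding crops raises the fraction above
    the pure-penalty value p/(1-p).  The extra-land GHG burden is the
    penalised per-hectare emission rate applied to the extra hectares
    (calorie-equalising basis).
    """
    if baseline_solution.output_t <= 0:
        raise ValueError("baseline output must be > 0")
    if solution_at_p.output_t <= 0 or solution_at_p.output_kcal <= 0:
        raise ValueError("zero penalised output: compensation undefined")
    frac_t = baseline_solution.output_t / solution_at_p.output_t - 1.0
    frac_kcal = baseline_solution.output_kcal / solution_at_p.output_kcal - 1.0
    total_ghg = solution_at_p.ghg_kg * (1.0 + frac_kcal)
    return CompensationResult(
        penalty=penalty,
        extra_land_fraction_t=frac_t,
        extra_land_fraction_kcal=frac_kcal,
        total_ghg_with_extra_land=total_ghg,
    )


def weed_control_scenario(
    tillage_id: str,
    calib: Calibration,
    price_year: str | int = "2011",
    extreme: bool = False,
    spray_cost_per_year: float = EXTRA_SPRAY_COST,
) -> tuple[FarmSolution, NetMarginReport]:
    """Black-grass herbicide add-on run.

    The biennial herbicide programme is annualised by halving its cost in
    this steady-state single-year model; ``extreme`` applies the full
    cost every year.  The extra spraying pass adds a machinery/fuel/labour
    cost on the net-margin side.
    """
    addon = BLACKGRASS_COST if extreme else BLACKGRASS_COST / 2.0
    sol = solve(
        build_program(
            calib, tillage_id, "max_GM", price_year, herbicide_addon=addon
        )
    )
    comp = size_complement(sol, calib, tillage_id)
    report = net_margin(
        sol,
        comp,
        calib.prices(price_year),
        calib.resources,
        extra_cost_per_ha=spray_cost_per_year if addon > 0 else 0.0,
    )
    return sol, report


def sb_selection_sweep(
    calib: Calibration,
    tillage_id: str = "ZT",
    price_year: str | int = "2011",
    penalty_grid: Sequence[float] = tuple(i / 50.0 for i in range(0, 16)),
) -> pd.DataFrame:
    """Spring-barley selection under yield penalties on every other crop.

    Returns one row per penalty with the optimised SB area and the full
    species mix; the attrs carry the SB entry threshold and the penalty at
    which SB exceeds 100 ha (None when not reached on the grid).
    """
    if "SB" not in calib.crops:
        raise ValueError("SB is not in the activity set")
    rows = []
    for p in penalty_grid:
        ym = {cid: 1.0 - p for cid in calib.crops if cid != "SB"}
        sol = solve(
            build_program(calib, tillage_id, "max_GM", price_year, yield_multiplier=ym)
        )
        row = {"penalty": p, "sb_area_ha": sol.species_areas.get("SB", 0.0),
               "gm": sol.gm}
        for sp, a in sol.species_areas.items():
            row[f"area_{sp}"] = a
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0.0)
    entry = df.loc[df["sb_area_ha"] > 1e-6, "penalty"]
    big = df.loc[df["sb_area_ha"] > 100.0, "penalty"]
    df.attrs["entry_threshold"] = float(entry.iloc[0]) if len(entry) else None
    df.attrs["threshold_100ha"] = float(big.iloc[0]) if len(big) else None
    return df


def pairwise_deltas(metrics: pd.DataFrame, base: str = "CT") -> pd.DataFrame:
    """Pairwise changes from a base tillage system, reported in the
    rounding style of the published tables: nearest integer percent for
    relative changes, nearest GBP/ha for per-hectare differences.

    ``metrics`` has one row per quantity and one column per tillage
    system; rows whose name ends in ``_per_ha`` are differenced, all
    others are expressed as percent of the base column.
    """
    if base not in metrics.columns:
        raise ValueError(f"base column {base!r} not in metrics table")
    out = {}
    for col in metrics.columns:
        if col == base:
            continue
        deltas = {}
        for name, row in metrics.iterrows():
            b, v = row[base], row[col]
            if str(name).endswith("_per_ha"):
                deltas[f"{name}_diff"] = round(v - b)
            else:
                deltas[f"{name}_pct"] = round(100.0 * (v - b) / b) if b else float("nan")
        out[f"{base}->{col}"] = deltas
    return pd.DataFrame(out)


def solution_table(solutions: dict[str, FarmSolution]) -> pd.DataFrame:
    """Crop mixes and the three metrics, one column per tillage system."""
    acts = sorted({a for s in solutions.values() for a in s.areas})
    rows = {}
    for a in acts:
        rows[a] = {tid: s.areas.get(a, 0.0) for tid, s in solutions.items()}
    rows["gross_margin_gbp"] = {t: s.gm for t, s in solutions.items()}
    rows["net_energy_gj"] = {t: s.ne_gj for t, s in solutions.items()}
    rows["ghg_kg_co2e"] = {t: s.ghg_kg for t, s in solutions.items()}
    return pd.DataFrame(rows).T


def net_margin_table(
    solutions: dict[str, FarmSolution], calib: Calibration, price_year: str | int
) -> pd.DataFrame:
    """Fuel, labour, machinery and contractor costs and net margins by
    tillage system for profit-maximised plans."""
    prices = calib.prices(price_year)
    cols = {}
    for tid, sol in solutions.items():
        comp = size_complement(sol, calib, tid)
        r = net_margin(sol, comp, prices, calib.resources)
        cols[tid] = {
            "gm_per_ha": r.gm / r.area_ha,
            "fuel_l": r.fuel_l,
            "fuel_cost": r.fuel_cost,
            "contractor_fees": r.contractor_fees,
            "machinery_cost": r.machinery_cost,
            "machinery_per_ha": r.machinery_per_ha,
            "labour_cost": r.labour_cost,
            "labour_per_ha": r.labour_per_ha,
            "net_margin": r.nm,
            "nm_per_ha": r.nm_per_ha,
        }
    return pd.DataFrame(cols)


@dataclass
class ScenarioReport:
    solution_tables: dict[str, pd.DataFrame]
    net_margin_tables: dict[str, pd.DataFrame]
    deltas: dict[str, pd.DataFrame]
    failures: list[dict]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in self.solution_tables.items():
            df.to_csv(out / f"solutions_{key}.csv")
        for key, df in self.net_margin_tables.items():
            df.to_csv(out / f"net_margin_{key}.csv")
        for key, df in self.deltas.items():
            df.to_csv(out / f"deltas_{key}.csv")
        with open(out / "failures.json", "w") as fh:
            json.dump(self.failures, fh, indent=2)


def scenario_matrix(
    calib: Calibration,
    price_years: Iterable[str] = ("2011",),
    tillage_ids: Iterable[str] = ("CT", "RP", "DRT", "SRT1", "SRT2", "ZT"),
    objectives: Iterable[str] = ("max_GM", "max_NE", "min_GHG"),
    greening_flags: Iterable[bool] = (False,),
    base: str = "CT",
) -> ScenarioReport:
    """Run every (year, objective, greening, tillage) combination.

    Failed solves are recorded in ``failures`` rather than dropped.
    """
    tillage_ids = list(tillage_ids)
    sol_tables: dict[str, pd.DataFrame] = {}
    nm_tables: dict[str, pd.DataFrame] = {}
    deltas: dict[str, pd.DataFrame] = {}
    failures: list[dict] = []
    for year in price_years:
        for greening in greening_flags:
            gtag = "greening" if greening else "base"
            for obj in objectives:
                sols: dict[str, FarmSolution] = {}
                for tid in tillage_ids:
                    try:
                        sols[tid] = solve(
                            build_program(calib, tid, obj, year, greening=greening)
                        )
                    except Exception as exc:  # recorded, not dropped
                        failures.append(
                            {"year": str(year), "tillage": tid, "objective": obj,
                             "greening": greening, "error": str(exc)}
                        )
                if not sols:
                    continue
                key = f"{year}_{gtag}_{obj}"
                sol_tables[key] = solution_table(sols)
                if obj == "max_GM":
                    nm_tables[key] = net_margin_table(sols, calib, year)
                    metrics = pd.concat(
                        [
                            sol_tables[key].loc[
                                ["gross_margin_gbp", "net_energy_gj", "ghg_kg_co2e"]
                            ],
                            nm_tables[key].loc[
                                ["fuel_l", "machinery_cost", "nm_per_ha"]
                            ],
                        ]
                    )
                    if base in metrics.columns and len(metrics.columns) > 1:
                        deltas[key] = pairwise_deltas(metrics, base=base)
    return ScenarioReport(sol_tables, nm_tables, deltas, failures)
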