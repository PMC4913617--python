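"""Per-hectare accounting for crop activities.

An *activity* is a plantable unit: crop variant x straw fate x nitrogen
level.  For each activity under a given tillage system and price set this
module computes the three farm metrics per hectare —

* gross margin (GM, GBP/ha): sales of grain (and baled straw) less the
  variable costs of fertiliser, crop protection, seed, fuel for field
  operations and grain drying, and the fixed contractor fees for swathing
  and baling;
* net energy (NE, MJ/ha): energy captured in outputs less the energy
  embedded in manufactured inputs, seed, fuel and machinery;
* GHG emissions (kg CO2-eq/ha): input manufacture, fuel combustion,
  machinery embedded burden and soil N2O from applied and background N —

together with fuel use, machine hours by (class, work period) and physical
output, which the farm linear programme consumes.

Machinery embedded energy/emissions are allocated by hours of use at
``weight x per-kg steel factor / lifespan`` for every machine involved in
an operation, whether the farm or a contractor owns it, so NE and GHG are
independent of who drives.  Grain drying is the only yield-proportional
cost; every other variable cost is fixed per hectare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .domain import (
    Calibration,
    Crop,
    EmissionFactors,
    EnergyFactors,
    FieldOperation,
    MachineClass,
    PriceSet,
    TillageSystem,
)

STRAW_BALED = "baled"
STRAW_INCORPORATED = "incorporated"

_N_SUFFIX = {0.5: "N50", 0.75: "N75", 1.0: "N100"}


@dataclass(frozen=True)
class Activity:
    """Crop variant x straw fate x N level (fraction of the recommended rate)."""

    crop_id: str
    straw: str | None  # "baled" | "incorporated" | None for non-straw crops
    n_level: float

    @property
    def id(self) -> str:
        parts = [self.crop_id]
        if self.straw == STRAW_BALED:
            parts.append("SR")
        elif self.straw == STRAW_INCORPORATED:
            parts.append("SI")
        parts.append(_N_SUFFIX.get(self.n_level, f"N{self.n_level * 100:g}"))
        return "_".join(parts)


@dataclass
class ActivityCoefficients:
    """All per-hectare coefficients of one activity, with the component
    breakdown retained as the audit trail for the farm-level arithmetic."""

    activity: Activity
    gm: float  # GBP/ha
    ne_mj: float
    ghg_kg: float
    fuel_l: float
    hours: dict[tuple[MachineClass, str], float]  # (class, period) -> h/ha
    output_t: float
    output_kcal: float
    revenue_components: dict[str, float] = field(default_factory=dict)
    cost_components: dict[str, float] = field(default_factory=dict)
    energy_output_components: dict[str, float] = field(default_factory=dict)
    energy_input_components: dict[str, float] = field(default_factory=dict)
    ghg_components: dict[str, float] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.activity.id


def machinery_hourly_embedded(
    machine, energy: EnergyFactors, emissions: EmissionFactors
) -> tuple[float, float]:
    """Hourly embedded (indirect) energy and emissions of a machine.

    Allocates the steel manufacture burden of the machine evenly over its
    working lifespan: ``weight x per-kg factor / lifespan``.
    """
    if machine.lifespan_h <= 0:
        raise ValueError("machine lifespan must be positive")
    mj_h = machine.weight_kg * energy.steel_mj_kg / machine.lifespan_h
    kg_h = machine.weight_kg * emissions.steel_kgco2_kg / machine.lifespan_h
    return mj_h, kg_h


def soil_n2o_co2e(applied_n: float, f: EmissionFactors) -> float:
    """Annual soil N2O emissions in kg CO2-eq/ha for a given N application.

    A fixed fraction of applied N plus a constant background flux is
    released as N2O-N, converted to N2O mass (44/28) and to CO2-eq.
    """
    if applied_n < 0:
        raise ValueError("applied N must be >= 0")
    n2o_n = f.n2o_ef * applied_n + f.background_n2o_n
    return n2o_n * f.n_to_n2o * f.gwp_n2o


def _resolve_period(op: FieldOperation, crop: Crop, spring_period: str) -> str:
    if op.timing == "establishment":
        return crop.establishment_period
    if op.timing == "harvest":
        return crop.harvest_period
    if op.timing == "spring":
        return spring_period
    raise ValueError(f"unknown operation timing {op.timing!r}")


def _is_drill(op: FieldOperation) -> bool:
    return op.implement_id == "drill"


def iter_operations(
    calib: Calibration,
    tillage: TillageSystem,
    crop: Crop,
    straw: str | None,
):
    """Yield (op, passes, period) for every operation the activity incurs.

    Under broadcast-WOSR tillage systems the drill pass is dropped for
    WOSR (seed goes out with the tillage passes); straw-only operations
    (swathing, baling) are dropped unless the straw is baled.
    """
    spring = calib.resources.spring_period
    for op in list(tillage.operations) + list(calib.shared_operations):
        if op.straw_only and straw != STRAW_BALED:
            continue
        if tillage.wosr_broadcast and crop.species == "WOSR" and _is_drill(op):
            continue
        passes = op.passes_for(crop)
        if passes <= 0:
            continue
        yield op, passes, _resolve_period(op, crop, spring)


def operation_hours_and_fuel(
    tillage: TillageSystem, crop_id: str, calib: Calibration
) -> tuple[dict[tuple[MachineClass, str], float], float]:
    """Machine hours by (class, period) and fuel (L/ha) for the tillage
    system's own operations (cultivation + drilling) on one crop."""
    if crop_id not in calib.crops:
        raise KeyError(f"unknown crop {crop_id!r}")
    crop = calib.crops[crop_id]
    spring = calib.resources.spring_period
    hours: dict[tuple[MachineClass, str], float] = {}
    fuel = 0.0
    for op in tillage.operations:
        if tillage.wosr_broadcast and crop.species == "WOSR" and _is_drill(op):
            continue
        passes = op.passes_for(crop)
        if passes <= 0:
            continue
        h = passes * op.work_rate_min_ha / 60.0
        period = _resolve_period(op, crop, spring)
        key = (op.power_class, period)
        hours[key] = hours.get(key, 0.0) + h
        fuel += h * calib.power_machine(op.power_class).fuel_l_h
    return hours, fuel


def pesticide_program_cost(crop: Crop, prices: PriceSet) -> float:
    """Whole-programme crop protection cost (GBP/ha) for the price year."""
    if not crop.pesticide_program:
        return 0.0
    try:
        costs = prices.pesticide_costs[crop.id]
    except KeyError:
        raise KeyError(f"no pesticide costs for crop {crop.id!r} in {prices.year}")
    total = 0.0
    for cat in crop.pesticide_program:
        if cat.name not in costs:
            raise KeyError(
                f"missing pesticide price {crop.id}/{cat.name!r} in {prices.year}"
            )
        total += costs[cat.name]
    return total


def enumerate_activities(calib: Calibration) -> list[Activity]:
    """All activities: straw fate for straw-bearing cereals, N levels from
    the calibration's response curve for N-using crops."""
    out: list[Activity] = []
    n_levels = sorted(calib.n_response)
    for crop in calib.crops.values():
        straws: list[str | None]
        if crop.category == "cereal" and crop.straw_yield > 0:
            straws = [STRAW_BALED, STRAW_INCORPORATED]
        else:
            straws = [None]
        levels = n_levels if crop.n_rate > 0 else [1.0]
        for straw in straws:
            for nl in levels:
                out.append(Activity(crop.id, straw, nl))
    return out


def activity_coefficients(
    activity: Activity,
    tillage: TillageSystem,
    calib: Calibration,
    price_year: str | int = "2011",
    yield_multiplier: float | dict[str, float] = 1.0,
    herbicide_addon: float = 0.0,
) -> ActivityCoefficients:
    """Compute the full per-hectare coefficient set for one activity.

    ``yield_multiplier`` scales grain and straw yields (uniformly, or per
    crop id when a mapping is given) — the lever for yield-penalty
    scenarios.  ``herbicide_addon`` is an extra crop-protection cost in
    GBP/ha/yr applied to every activity (weed-control scenarios); it is a
    cost with no spray-count effect on energy or emissions.
    """
    crop = calib.crops[activity.crop_id]
    prices = calib.prices(price_year)
    ef, en = calib.emission_factors, calib.energy_factors

    if isinstance(yield_multiplier, dict):
        ymult = yield_multiplier.get(crop.id, 1.0)
    else:
        ymult = float(yield_multiplier)
    n_mult = calib.n_response[activity.n_level] if crop.n_rate > 0 else 1.0

    grain_t = crop.grain_yield * n_mult * ymult
    straw_t = (
        crop.straw_yield * n_mult * ymult if activity.straw == STRAW_BALED else 0.0
    )
    applied_n = crop.n_rate * activity.n_level if crop.n_rate > 0 else 0.0

    hours: dict[tuple[MachineClass, str], float] = {}
    op_fuel = 0.0
    embedded_mj = 0.0
    embedded_kg = 0.0
    baling_fees = 0.0
    for op, passes, period in iter_operations(calib, tillage, crop, activity.straw):
        h = passes * op.work_rate_min_ha / 60.0
        key = (op.power_class, period)
        hours[key] = hours.get(key, 0.0) + h
        implement = calib.machines[op.implement_id]
        involved = {implement.id: implement}
        if op.power_class is not MachineClass.IMPLEMENT:
            power = calib.power_machine(op.power_class)
            involved[power.id] = power
            op_fuel += h * power.fuel_l_h
        for m in involved.values():
            mj_h, kg_h = machinery_hourly_embedded(m, en, ef)
            embedded_mj += h * mj_h
            embedded_kg += h * kg_h
        if op.power_class in (MachineClass.SWATHER, MachineClass.BALER):
            fee = prices.contractor_fees.get(op.power_class.value)
            if fee is None:
                raise KeyError(
                    f"missing contractor fee for {op.power_class.value} in {prices.year}"
                )
            baling_fees += h * fee

    drying_fuel = crop.drying_fuel_l_t * grain_t
    total_fuel = op_fuel + drying_fuel

    sp = crop.species
    if sp not in prices.grain_prices:
        raise KeyError(f"missing grain price for {sp} in {prices.year}")
    rev = {"grain": prices.grain_prices[sp] * grain_t}
    if straw_t > 0:
        if sp not in prices.straw_prices:
            raise KeyError(f"missing straw price for {sp} in {prices.year}")
        rev["straw"] = prices.straw_prices[sp] * straw_t

    cost = {
        "fertiliser": (
            applied_n * prices.n_price_kg
            + crop.p_rate * prices.p_price_kg
            + crop.k_rate * prices.k_price_kg
        ),
        "pesticides": pesticide_program_cost(crop, prices) + herbicide_addon,
        "seed": crop.seed_cost,
        "operation_fuel": op_fuel * prices.fuel_price_l,
        "drying_fuel": drying_fuel * prices.fuel_price_l,
        "baling_contract": baling_fees,
    }
    gm = sum(rev.values()) - sum(cost.values())

    e_out = {
        "grain": grain_t * crop.grain_energy_gj_t * 1000.0,
        "straw": straw_t * crop.straw_energy_gj_t * 1000.0,
    }
    e_in = {
        "fertiliser": (
            applied_n * en.n_manuf_mj_kg
            + crop.p_rate * en.p_manuf_mj_kg
            + crop.k_rate * en.k_manuf_mj_kg
        ),
        "pesticides": crop.total_sprays * en.pesticide_mj_spray,
        "seed": crop.seed_energy_mj,
        "fuel": total_fuel * en.fuel_mj_l,
        "machinery": embedded_mj,
    }
    ne = sum(e_out.values()) - sum(e_in.values())

    ghg = {
        "soil_n2o": soil_n2o_co2e(applied_n, ef),
        "input_manufacture": (
            applied_n * ef.n_manuf_kgco2_kg
            + crop.p_rate * ef.p_manuf_kgco2_kg
            + crop.k_rate * ef.k_manuf_kgco2_kg
            + crop.total_sprays * ef.pesticide_kgco2_spray
        ),
        "fuel_combustion": total_fuel * ef.fuel_kgco2_l,
        "machinery": embedded_kg,
    }

    return ActivityCoefficients(
        activity=activity,
        gm=gm,
        ne_mj=ne,
        ghg_kg=sum(ghg.values()),
        fuel_l=total_fuel,
        hours=hours,
        output_t=grain_t + straw_t,
        output_kcal=grain_t * 1000.0 * crop.kcal_per_kg,
        revenue_components=rev,
        cost_components=cost,
        energy_output_components=e_out,
        energy_input_components=e_in,
        ghg_components=ghg,
    )


def activity_table(
    calib: Calibration,
    tillage_id: str,
    price_year: str | int = "2011",
    yield_multiplier: float | dict[str, float] = 1.0,
    herbicide_addon: float = 0.0,
) -> pd.DataFrame:
    """Per-activity coefficient table with one column per GM/NE/GHG
    component — the audit trail behind every farm-level figure."""
    tillage = calib.tillage_systems[tillage_id]
    rows = []
    for act in enumerate_activities(calib):
        c = activity_coefficients(
            act, tillage, calib, price_year, yield_multiplier, herbicide_addon
        )
        row = {
            "activity": c.id,
            "crop": act.crop_id,
            "straw": act.straw or "",
            "n_level": act.n_level,
            "gm_gbp_ha": c.gm,
            "ne_mj_ha": c.ne_mj,
            "ghg_kg_ha": c.ghg_kg,
            "fuel_l_ha": c.fuel_l,
            "output_t_ha": c.output_t,
            "output_kcal_ha": c.output_kcal,
        }
        for k, v in c.revenue_components.items():
            row[f"rev_{k}"] = v
        for k, v in c.cost_components.items():
            row[f"cost_{k}"] = v
        for k, v in c.energy_output_components.items():
            row[f"e_out_{k}"] = v
        for k, v in c.energy_input_components.items():
            row[f"e_in_{k}"] = v
        for k, v in c.ghg_components.items():
            row[f"ghg_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
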