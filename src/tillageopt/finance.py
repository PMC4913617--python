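"""Whole-farm net margin: machinery complement and ownership costs.

Net margin (NM) is gross margin less machinery ownership/running costs and
labour, both adjusted to actual machinery usage:

    NM = GM - sum(depreciation + spares & repairs + insurance + interest)
            - own machine hours x wage

Fuel and contractors' fees are already inside GM, so the only additions
here are the ownership-side costs.  Depreciation is straight-line with the
annual rate interpolated from each machine's (annual hours, rate) anchor
points — e.g. a medium tractor depreciates at 15%/yr when used 500 h/yr
and 27%/yr at 1500 h/yr.  Interest is charged on average invested capital
(half the purchase price); the capital base is configurable through the
resources' interest rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accounting import iter_operations
from .domain import Calibration, Machine, MachineClass, PriceSet, FarmResources
from .optimizer import FarmSolution

#: machine classes never owned by the farm (their work is always contracted)
NEVER_OWNED = (MachineClass.SWATHER, MachineClass.BALER)


@dataclass
class MachineCost:
    machine_id: str
    annual_hours: float
    depreciation: float
    spares_repairs: float
    insurance: float
    interest: float

    @property
    def total(self) -> float:
        return self.depreciation + self.spares_repairs + self.insurance + self.interest


@dataclass
class MachineryComplement:
    """The owned machine set implied by a farm plan, with annual costs."""

    items: list[MachineCost] = field(default_factory=list)
    area_ha: float = 1.0

    @property
    def total_cost(self) -> float:
        return sum(m.total for m in self.items)

    @property
    def cost_per_ha(self) -> float:
        return self.total_cost / self.area_ha

    @property
    def machine_ids(self) -> set[str]:
        return {m.machine_id for m in self.items}


@dataclass
class NetMarginReport:
    gm: float
    fuel_l: float
    fuel_cost: float
    contractor_fees: float
    machinery_cost: float
    labour_cost: float
    other_costs: float
    area_ha: float

    @property
    def nm(self) -> float:
        return self.gm - self.machinery_cost - self.labour_cost - self.other_costs

    @property
    def nm_per_ha(self) -> float:
        return self.nm / self.area_ha

    @property
    def machinery_per_ha(self) -> float:
        return self.machinery_cost / self.area_ha

    @property
    def labour_per_ha(self) -> float:
        return self.labour_cost / self.area_ha


def depreciation_rate(machine: Machine, annual_hours: float) -> float:
    """Usage-dependent annual depreciation rate (fraction of price/yr).

    Piecewise-linear interpolation between the machine's anchor points,
    clamped at the end anchors.
    """
    if annual_hours < 0:
        raise ValueError("annual hours must be >= 0")
    sched = machine.depreciation_schedule
    if not sched:
        raise ValueError(f"machine {machine.id} has an empty depreciation schedule")
    hours = [h for h, _ in sched]
    rates = [r for _, r in sched]
    return float(np.interp(annual_hours, hours, rates))


def machine_usage_hours(
    solution: FarmSolution, calib: Calibration, tillage_id: str
) -> dict[str, float]:
    """Annual own-farm hours per machine implied by the plan.

    Operation hours are attributed to both the implement and its power
    unit; where a (class, period) slot is partly contracted, each
    operation's hours in that slot are scaled by the farm's own share
    (contractors bring their own implement and driver).
    """
    tillage = calib.tillage_systems[tillage_id]
    need: dict[tuple[MachineClass, str], float] = {}
    per_machine: dict[str, dict[tuple[MachineClass, str], float]] = {}
    from .accounting import enumerate_activities  # local to avoid cycle at import

    acts = {a.id: a for a in enumerate_activities(calib)}
    for act_id, area in solution.areas.items():
        act = acts[act_id]
        crop = calib.crops[act.crop_id]
        for op, passes, period in iter_operations(calib, tillage, crop, act.straw):
            h = area * passes * op.work_rate_min_ha / 60.0
            key = (op.power_class, period)
            need[key] = need.get(key, 0.0) + h
            ids = {op.implement_id}
            if op.power_class is not MachineClass.IMPLEMENT:
                ids.add(calib.power_machine(op.power_class).id)
            for mid in ids:
                d = per_machine.setdefault(mid, {})
                d[key] = d.get(key, 0.0) + h

    own_frac = {}
    for key, tot in need.items():
        if key[0] in NEVER_OWNED:  # swathing/baling is always contracted
            own_frac[key] = 0.0
        elif tot <= 1e-12:
            own_frac[key] = 1.0
        else:
            own_frac[key] = min(1.0, solution.own_hours.get(key, 0.0) / tot)

    usage: dict[str, float] = {}
    for mid, slots in per_machine.items():
        total = sum(h * own_frac.get(key, 0.0) for key, h in slots.items())
        if total > 1e-9:
            usage[mid] = total
    return usage


def size_complement(
    solution: FarmSolution, calib: Calibration, tillage_id: str
) -> MachineryComplement:
    """Own exactly the machines that perform own-farm work in the plan."""
    usage = machine_usage_hours(solution, calib, tillage_id)
    interest_rate = calib.resources.interest_rate
    items = []
    for mid in sorted(usage):
        m = calib.machines[mid]
        if m.machine_class in NEVER_OWNED:
            continue
        h = usage[mid]
        items.append(
            MachineCost(
                machine_id=mid,
                annual_hours=h,
                depreciation=depreciation_rate(m, h) * m.price_gbp,
                spares_repairs=m.spares_rate * m.price_gbp,
                insurance=m.insurance_rate * m.price_gbp,
                interest=interest_rate * m.price_gbp / 2.0,
            )
        )
    return MachineryComplement(items=items, area_ha=calib.resources.area_ha)


def net_margin(
    solution: FarmSolution,
    complement: MachineryComplement,
    prices: PriceSet,
    resources: FarmResources,
    extra_cost_per_ha: float = 0.0,
) -> NetMarginReport:
    """Whole-farm net margin for an optimised plan.

    ``extra_cost_per_ha`` carries scenario add-ons (e.g. the machinery,
    fuel and labour cost of an extra spraying pass) outside the GM.
    """
    own_h = sum(solution.own_hours.values())
    labour = own_h * prices.labour_wage
    fuel_cost = solution.fuel_l * prices.fuel_price_l
    return NetMarginReport(
        gm=solution.gm,
        fuel_l=solution.fuel_l,
        fuel_cost=fuel_cost,
        contractor_fees=solution.contractor_fees,
        machinery_cost=complement.total_cost,
        labour_cost=labour,
        other_costs=extra_cost_per_ha * resources.area_ha,
        area_ha=resources.area_ha,
    )


def contractor_fee_2014(machine: Machine, prices: PriceSet) -> float:
    """Construct a contractor fee from machine costs at high usage: hourly
    ownership+running cost plus a 25% overhead, plus the labour rate with
    a 35% surcharge.  (2011 fees are quoted directly instead.)"""
    fee = machine.high_usage_cost * (1.0 + prices.overhead_frac)
    fee += prices.labour_wage * (1.0 + prices.labour_surcharge)
    return round(fee, 2)
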