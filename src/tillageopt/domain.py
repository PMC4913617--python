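"""Domain types for the bio-economic tillage model.

The farm is a fixed arable area (default 400 ha) growing combinable crops —
winter wheat as first/second/continuous wheat (WW1/WW2/WWc), winter and
spring barley (WB/SB), winter oilseed rape (WOSR) and winter field beans
(WFB) — under one of six tillage systems of decreasing intensity (CT, RP,
DRT, SRT1, SRT2, ZT).  All parameters are carried in fixed conventional
units: money in GBP, energy in MJ internally (GJ in reports), emissions in
kg CO2-eq, areas in ha, machine time in hours (work-rates are stored in
minutes per hectare per pass, as usually quoted).
"""

from __future__ import annotations

import enum
import math

from pydantic import BaseModel, Field, field_validator, model_validator

CROP_IDS = ("WW1", "WW2", "WWc", "WB", "SB", "WOSR", "WFB")
SPECIES = ("WW", "WB", "SB", "WOSR", "WFB")
TILLAGE_IDS = ("CT", "RP", "DRT", "SRT1", "SRT2", "ZT")

#: crop variant -> species used for prices, pass matrices and Greening counts
SPECIES_OF = {
    "WW1": "WW", "WW2": "WW", "WWc": "WW",
    "WB": "WB", "SB": "SB", "WOSR": "WOSR", "WFB": "WFB",
}

BREAK_CROPS = ("WOSR", "WFB")
CEREALS = ("WW1", "WW2", "WWc", "WB", "SB")

PESTICIDE_CATEGORIES = (
    "fungicides",
    "herbicides",
    "growth regulators",
    "insecticides",
    "seed treatments and molluscicides",
)


class ValidationError(ValueError):
    """Raised when a calibration bundle violates a model invariant."""


class MachineClass(str, enum.Enum):
    SMALL_TRACTOR = "small_tractor"
    MEDIUM_TRACTOR = "medium_tractor"
    LARGE_TRACTOR = "large_tractor"
    COMBINE = "combine"
    SWATHER = "swather"
    BALER = "baler"
    IMPLEMENT = "implement"


#: classes whose hours enter the farm labour/machine resource balances and can be
#: bought in from contractors by the hour.  Swather and baler work is always
#: contracted at a fixed per-pass fee instead.
RESOURCE_CLASSES = (
    MachineClass.SMALL_TRACTOR,
    MachineClass.MEDIUM_TRACTOR,
    MachineClass.LARGE_TRACTOR,
    MachineClass.COMBINE,
)


class PesticideCategory(BaseModel):
    """One line of a crop protection programme (costs live in PriceSet)."""

    name: str
    sprays: int = Field(ge=1)

    @field_validator("name")
    @classmethod
    def _known_category(cls, v: str) -> str:
        if v not in PESTICIDE_CATEGORIES:
            raise ValueError(f"unknown pesticide category {v!r}")
        return v


class Crop(BaseModel):
    """A crop variant with its per-hectare physical coefficients.

    ``grain_yield``/``straw_yield`` are the full-N reference yields (t/ha);
    the calibration's nitrogen response curve scales them for reduced N.
    """

    id: str
    category: str  # "cereal" | "break"
    season: str  # "autumn" | "spring"
    establishment_period: str
    harvest_period: str
    grain_yield: float = Field(ge=0)
    straw_yield: float = Field(default=0.0, ge=0)
    grain_energy_gj_t: float = Field(gt=0)
    straw_energy_gj_t: float = Field(default=0.0, ge=0)
    kcal_per_kg: float = Field(gt=0)
    n_rate: float = Field(ge=0)  # kg N/ha at the full recommended rate
    p_rate: float = Field(ge=0)
    k_rate: float = Field(ge=0)
    seed_cost: float = Field(ge=0)  # GBP/ha
    seed_energy_mj: float = Field(ge=0)  # MJ/ha embedded in seed
    drying_fuel_l_t: float = Field(ge=0)  # L fuel per tonne of grain dried
    pesticide_program: list[PesticideCategory] = Field(default_factory=list)

    @property
    def species(self) -> str:
        return SPECIES_OF[self.id]

    @model_validator(mode="after")
    def _check(self) -> "Crop":
        if self.id not in CROP_IDS:
            raise ValueError(f"unknown crop id {self.id!r}")
        is_break = self.id in BREAK_CROPS
        if is_break != (self.category == "break"):
            raise ValueError(f"{self.id}: break crops are WOSR and WFB only")
        if not is_break and self.category != "cereal":
            raise ValueError(f"{self.id}: category must be cereal or break")
        if is_break and self.straw_yield > 0:
            raise ValueError(f"{self.id}: straw is baled from cereals only")
        return self

    @property
    def total_sprays(self) -> int:
        return sum(c.sprays for c in self.pesticide_program)


class Machine(BaseModel):
    """An implement, tractor or harvest machine.

    ``depreciation_schedule`` holds (annual hours, annual rate fraction)
    anchor points for usage-dependent straight-line depreciation;
    ``high_usage_cost`` is the hourly ownership+running cost at a 'high'
    usage rate, used to construct 2014 contractor fees.
    """

    id: str
    machine_class: MachineClass
    weight_kg: float = Field(gt=0)
    price_gbp: float = Field(ge=0)
    lifespan_h: float = Field(default=3000.0, gt=0)
    fuel_l_h: float = Field(default=0.0, ge=0)
    depreciation_schedule: list[tuple[float, float]] = Field(default_factory=list)
    spares_rate: float = Field(default=0.0, ge=0)
    insurance_rate: float = Field(default=0.0, ge=0)
    high_usage_cost: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "Machine":
        sched = self.depreciation_schedule
        for (h0, r0), (h1, r1) in zip(sched, sched[1:]):
            if not (h1 > h0 and r1 > r0):
                raise ValueError(
                    f"{self.id}: depreciation anchors must be strictly "
                    "increasing in hours and rates"
                )
        return self


class FieldOperation(BaseModel):
    """One field operation: an implement powered by a machine class.

    ``timing`` resolves to a work period per crop: establishment operations
    run in the crop's establishment period, harvest operations in its
    harvest period, and "spring" operations in the named spring period.
    ``passes`` is keyed by species (pass matrices are quoted per species);
    ``straw_only`` marks operations that occur only when straw is baled.
    ``sprays_as_passes`` makes the pass count equal to the crop's total
    number of pesticide applications.
    """

    implement_id: str
    power_class: MachineClass
    work_rate_min_ha: float = Field(gt=0)
    timing: str  # "establishment" | "harvest" | "spring"
    passes: dict[str, int] = Field(default_factory=dict)
    straw_only: bool = False
    sprays_as_passes: bool = False

    @field_validator("passes")
    @classmethod
    def _nonneg(cls, v: dict[str, int]) -> dict[str, int]:
        for sp, n in v.items():
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r} in pass matrix")
            if n < 0:
                raise ValueError(f"passes must be >= 0 (got {n} for {sp})")
        return v

    def passes_for(self, crop: Crop) -> int:
        if self.sprays_as_passes:
            return crop.total_sprays
        return self.passes.get(crop.species, 0)


class TillageSystem(BaseModel):
    """Cultivation + drilling operations of one tillage system.

    ``wosr_broadcast`` — under the reduced-tillage systems RP/DRT/SRT1/SRT2
    oilseed rape seed is broadcast simultaneously with the tillage passes,
    so no separate drill pass (cost, fuel or time) is incurred for WOSR.
    """

    id: str
    operations: list[FieldOperation]
    wosr_broadcast: bool = False

    @model_validator(mode="after")
    def _check(self) -> "TillageSystem":
        if self.id not in TILLAGE_IDS:
            raise ValueError(f"unknown tillage system {self.id!r}")
        for op in self.operations:
            if op.timing != "establishment":
                raise ValueError(f"{self.id}: tillage operations are establishment-timed")
        return self


class EmissionFactors(BaseModel):
    """GHG emission factors (kg CO2-eq unless noted).

    Soil N2O follows an emission-factor approach: a fraction of applied N
    is released as N2O-N on top of a constant background flux, converted to
    N2O by mass (44/28) and to CO2-eq by the N2O global warming potential.
    """

    n2o_ef: float = Field(default=0.016, ge=0)  # fraction of applied N
    background_n2o_n: float = Field(default=1.4, ge=0)  # kg N2O-N/ha/yr
    gwp_n2o: float = Field(default=298.0, ge=0)
    n_to_n2o: float = Field(default=44.0 / 28.0, ge=0)
    steel_kgco2_kg: float = Field(default=1.56, ge=0)
    fuel_kgco2_l: float = Field(default=3.1, ge=0)
    n_manuf_kgco2_kg: float = Field(default=6.8, ge=0)
    p_manuf_kgco2_kg: float = Field(default=1.0, ge=0)
    k_manuf_kgco2_kg: float = Field(default=0.6, ge=0)
    pesticide_kgco2_spray: float = Field(default=6.3, ge=0)


class EnergyFactors(BaseModel):
    """Energy factors (MJ unless noted).  Steel is 23 MJ/kg: only that
    working unit is consistent with quoted hourly embedded-energy figures
    (e.g. 7350 kg over a 3000 h lifespan -> 56.35 MJ/h)."""

    steel_mj_kg: float = Field(default=23.0, gt=0)
    fuel_mj_l: float = Field(default=45.0, gt=0)
    n_manuf_mj_kg: float = Field(default=40.0, gt=0)
    p_manuf_mj_kg: float = Field(default=15.0, gt=0)
    k_manuf_mj_kg: float = Field(default=9.0, gt=0)
    pesticide_mj_spray: float = Field(default=150.0, gt=0)


class WorkPeriod(BaseModel):
    """A block of the working year with its own labour and machine hours."""

    id: str
    labour_h: float = Field(ge=0)
    machine_h: dict[str, float] = Field(default_factory=dict)

    @field_validator("machine_h")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for cls_name, h in v.items():
            MachineClass(cls_name)
            if h < 0:
                raise ValueError("machine hours must be >= 0")
        return v


class FarmResources(BaseModel):
    area_ha: float = Field(default=400.0, gt=0)
    periods: list[WorkPeriod]
    spring_period: str = "spring"
    interest_rate: float = Field(default=0.03, ge=0)

    @property
    def period_ids(self) -> list[str]:
        return [p.id for p in self.periods]

    def period(self, pid: str) -> WorkPeriod:
        for p in self.periods:
            if p.id == pid:
                return p
        raise KeyError(pid)


class PriceSet(BaseModel):
    """Crop, input, fuel, labour and contractor prices for a market year.

    Grain/straw prices are keyed by species so the three wheat variants
    share one price by construction.  Pesticide programme costs are keyed
    by crop variant because first wheats carry a different seed-treatment
    line from later wheats.
    """

    year: str
    grain_prices: dict[str, float]  # GBP/t by species
    straw_prices: dict[str, float] = Field(default_factory=dict)
    n_price_kg: float = Field(ge=0)
    p_price_kg: float = Field(ge=0)
    k_price_kg: float = Field(ge=0)
    fuel_price_l: float = Field(ge=0)
    labour_wage: float = Field(ge=0)  # GBP/h
    pesticide_costs: dict[str, dict[str, float]] = Field(default_factory=dict)
    contractor_fees: dict[str, float] = Field(default_factory=dict)  # GBP/h by class
    overhead_frac: float = Field(default=0.25, ge=0)
    labour_surcharge: float = Field(default=0.35, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "PriceSet":
        for d in (self.grain_prices, self.straw_prices):
            for k, v in d.items():
                if k not in SPECIES:
                    raise ValueError(f"unknown species {k!r} in price table")
                if v < 0:
                    raise ValueError(f"negative price for {k}")
        for crop, cats in self.pesticide_costs.items():
            if crop not in CROP_IDS:
                raise ValueError(f"unknown crop {crop!r} in pesticide costs")
            for cat, cost in cats.items():
                if cat not in PESTICIDE_CATEGORIES:
                    raise ValueError(f"unknown pesticide category {cat!r}")
                if cost < 0:
                    raise ValueError(f"negative pesticide cost for {crop}/{cat}")
        for cls_name, fee in self.contractor_fees.items():
            MachineClass(cls_name)
            if fee < 0:
                raise ValueError("negative contractor fee")
        return self


class ProvenanceRecord(BaseModel):
    parameter: str
    tag: str  # "paper" | "placeholder"
    note: str = ""

    @field_validator("tag")
    @classmethod
    def _tag(cls, v: str) -> str:
        if v not in ("paper", "placeholder"):
            raise ValueError(f"provenance tag must be paper|placeholder, got {v!r}")
        return v


class Calibration(BaseModel):
    """The full validated parameter bundle."""

    crops: dict[str, Crop]
    machines: dict[str, Machine]
    tillage_systems: dict[str, TillageSystem]
    shared_operations: list[FieldOperation]
    emission_factors: EmissionFactors
    energy_factors: EnergyFactors
    resources: FarmResources
    price_sets: dict[str, PriceSet]
    n_response: dict[float, float]  # N fraction -> yield multiplier
    provenance: list[ProvenanceRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _cross_check(self) -> "Calibration":
        period_ids = set(self.resources.period_ids)
        for cid, crop in self.crops.items():
            if cid != crop.id:
                raise ValueError(f"crop key {cid!r} != crop id {crop.id!r}")
            for pid in (crop.establishment_period, crop.harvest_period):
                if pid not in period_ids:
                    raise ValueError(f"crop {cid}: unknown work period {pid!r}")
        if self.resources.spring_period not in period_ids:
            raise ValueError(f"unknown spring period {self.resources.spring_period!r}")
        powered = {}
        for mid, m in self.machines.items():
            if mid != m.id:
                raise ValueError(f"machine key {mid!r} != machine id {m.id!r}")
            if m.machine_class is not MachineClass.IMPLEMENT:
                if m.machine_class in powered:
                    raise ValueError(
                        f"more than one machine of class {m.machine_class.value}"
                    )
                powered[m.machine_class] = mid
        all_ops = list(self.shared_operations)
        for ts in self.tillage_systems.values():
            all_ops.extend(ts.operations)
        for op in all_ops:
            if op.implement_id not in self.machines:
                raise ValueError(f"dangling machine id {op.implement_id!r}")
            if op.power_class is not MachineClass.IMPLEMENT and op.power_class not in powered:
                raise ValueError(f"no machine of class {op.power_class.value}")
        for f, mult in self.n_response.items():
            if not (0 < f <= 1) or mult <= 0:
                raise ValueError("n_response keys in (0,1], multipliers > 0")
        if 1.0 not in self.n_response:
            raise ValueError("n_response must include the full rate 1.0")
        return self

    def power_machine(self, cls: MachineClass) -> Machine:
        """The unique tractor/harvest machine of a powered class."""
        for m in self.machines.values():
            if m.machine_class is cls:
                return m
        raise KeyError(cls)

    def prices(self, year: str | int) -> PriceSet:
        key = str(year)
        if key not in self.price_sets:
            raise KeyError(f"no price set for year {key!r}")
        return self.price_sets[key]


def percent_change(old: float, new: float) -> float:
    """Percentage change from ``old`` to ``new``, one-decimal reporting.

    Raises ValueError for old == 0 (undefined change).
    """
    if old == 0 or not math.isfinite(old):
        raise ValueError("percent change is undefined for a zero/non-finite base")
    return round(100.0 * (new - old) / old, 1)
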