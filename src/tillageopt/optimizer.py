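"""The farm linear programme.

Chooses per-activity areas on a fixed land base to maximise gross margin,
maximise net energy or minimise GHG emissions subject to:

* land balance — activity areas sum to the farm area;
* steady-state rotation flows — a transition variable carries hectares
  from each predecessor crop to each permitted successor, and every crop's
  area equals both its inflow and its outflow (the crop mix is a single
  year representation of the average rotation);
* per-period labour and machine-class balances, with unbounded contractor
  hours priced at the contractor fee (contracted work relieves both the
  machine and the farm's own labour, since the contractor brings a crew);
* optional CAP-Greening caps: every pair of species is limited to 95% of
  the land, which with full land use forces at least three species.

Solved with HiGHS via :func:`scipy.optimize.linprog`.  Among alternate
optima a secondary solve prefers the lexicographically smallest activity
mix so results are reproducible across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .accounting import ActivityCoefficients, activity_coefficients, enumerate_activities
from .domain import (
    Calibration,
    MachineClass,
    RESOURCE_CLASSES,
    SPECIES_OF,
)

OBJECTIVES = ("max_GM", "max_NE", "min_GHG")

#: permitted rotation transitions, predecessor -> successors.  Break crops
#: (WOSR, WFB) are grown only after a cereal and enable a first wheat; the
#: wheat variants chain WW1 -> WW2 -> WWc (continuous wheat self-succeeds);
#: barley can follow any crop with a cereal or break predecessor.
TRANSITIONS: dict[str, tuple[str, ...]] = {
    "WOSR": ("WW1", "WB", "SB"),
    "WFB": ("WW1", "WB", "SB"),
    "WW1": ("WW2", "WB", "SB", "WOSR", "WFB"),
    "WW2": ("WWc", "WB", "SB", "WOSR", "WFB"),
    "WWc": ("WWc", "WB", "SB", "WOSR", "WFB"),
    "WB": ("WB", "SB", "WOSR", "WFB"),
    "SB": ("WB", "SB", "WOSR", "WFB"),
}


class InfeasibleProgramError(RuntimeError):
    """Raised when the farm programme has no feasible crop plan; the
    message names the constraint group diagnosed as responsible."""


class UnboundedProgramError(RuntimeError):
    pass


@dataclass
class FarmProgram:
    """Matrix form of the farm LP plus the metadata needed for reporting."""

    objective: str
    calib: Calibration
    tillage_id: str
    price_year: str
    coeffs: list[ActivityCoefficients]
    flows: list[tuple[str, str]]
    ch_keys: list[tuple[MachineClass, str]]  # contractor-hour variables
    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    sense: int  # +1 minimise, -1 maximise (c is already sign-adjusted)
    greening: bool
    options: dict = field(default_factory=dict)

    @property
    def n_activities(self) -> int:
        return len(self.coeffs)

    @property
    def n_vars(self) -> int:
        return len(self.coeffs) + len(self.flows) + len(self.ch_keys)


@dataclass
class FarmSolution:
    """An optimised farm plan with all three metrics reported."""

    objective: str
    tillage_id: str
    price_year: str
    areas: dict[str, float]  # activity id -> ha
    species_areas: dict[str, float]
    gm: float  # GBP/farm (net of contractor fees)
    ne_gj: float
    ghg_kg: float
    fuel_l: float
    contractor_fees: float  # GBP/farm: hourly contracting + baling/swathing
    own_hours: dict[tuple[MachineClass, str], float]
    contractor_hours: dict[tuple[MachineClass, str], float]
    output_t: float
    output_kcal: float
    objective_value: float
    flows: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def total_area(self) -> float:
        return sum(self.areas.values())

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "tillage": self.tillage_id,
            "price_year": self.price_year,
            "areas_ha": self.areas,
            "species_areas_ha": self.species_areas,
            "gross_margin_gbp": self.gm,
            "net_energy_gj": self.ne_gj,
            "ghg_kg_co2e": self.ghg_kg,
            "fuel_l": self.fuel_l,
            "contractor_fees_gbp": self.contractor_fees,
            "output_t": self.output_t,
            "output_kcal": self.output_kcal,
            "own_hours": {f"{c.value}:{p}": h for (c, p), h in self.own_hours.items()},
            "contractor_hours": {
                f"{c.value}:{p}": h for (c, p), h in self.contractor_hours.items()
            },
        }


def _species_area_rows(coeffs) -> dict[str, np.ndarray]:
    rows: dict[str, np.ndarray] = {}
    for j, c in enumerate(coeffs):
        sp = SPECIES_OF[c.activity.crop_id]
        rows.setdefault(sp, np.zeros(len(coeffs)))[j] = 1.0
    return rows


def build_program(
    calib: Calibration,
    tillage_id: str,
    objective: str = "max_GM",
    price_year: str | int = "2011",
    greening: bool = False,
    yield_multiplier: float | dict[str, float] = 1.0,
    herbicide_addon: float = 0.0,
) -> FarmProgram:
    """Assemble the farm LP for one tillage system, price year and objective."""
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")
    tillage = calib.tillage_systems[tillage_id]
    prices = calib.prices(price_year)
    res = calib.resources

    coeffs = [
        activity_coefficients(
            a, tillage, calib, price_year, yield_multiplier, herbicide_addon
        )
        for a in enumerate_activities(calib)
    ]
    n_a = len(coeffs)
    crop_ids = sorted({c.activity.crop_id for c in coeffs})

    flows = [
        (pred, succ)
        for pred in crop_ids
        for succ in TRANSITIONS.get(pred, ())
        if succ in crop_ids
    ]
    n_f = len(flows)

    periods = res.period_ids
    ch_keys = [(cls, p) for cls in RESOURCE_CLASSES for p in periods]
    n_c = len(ch_keys)
    n = n_a + n_f + n_c

    def a_slice(v):
        out = np.zeros(n)
        out[:n_a] = v
        return out

    # --- equalities: land balance + rotation flow conservation
    eq_rows, eq_b = [], []
    eq_rows.append(a_slice(np.ones(n_a)))
    eq_b.append(res.area_ha)
    for cid in crop_ids:
        in_row = np.zeros(n)
        out_row = np.zeros(n)
        for j, c in enumerate(coeffs):
            if c.activity.crop_id == cid:
                in_row[j] = 1.0
                out_row[j] = 1.0
        for k, (pred, succ) in enumerate(flows):
            if succ == cid:
                in_row[n_a + k] = -1.0
            if pred == cid:
                out_row[n_a + k] = -1.0
        eq_rows.append(in_row)
        eq_b.append(0.0)
        eq_rows.append(out_row)
        eq_b.append(0.0)

    # --- inequalities
    ub_rows, ub_b = [], []
    need = {}  # (cls, period) -> per-activity hour vector
    for cls in RESOURCE_CLASSES:
        for p in periods:
            vec = np.zeros(n_a)
            for j, c in enumerate(coeffs):
                vec[j] = c.hours.get((cls, p), 0.0)
            need[(cls, p)] = vec

    # machine-class balances: need - contracted <= own capacity
    for i, (cls, p) in enumerate(ch_keys):
        row = np.zeros(n)
        row[:n_a] = need[(cls, p)]
        row[n_a + n_f + i] = -1.0
        ub_rows.append(row)
        ub_b.append(res.period(p).machine_h.get(cls.value, 0.0))
        # contracted hours cannot exceed the hours actually required
        row2 = np.zeros(n)
        row2[:n_a] = -need[(cls, p)]
        row2[n_a + n_f + i] = 1.0
        ub_rows.append(row2)
        ub_b.append(0.0)

    # labour balances: own-operated hours require the farm's own labour
    for p in periods:
        row = np.zeros(n)
        for cls in RESOURCE_CLASSES:
            row[:n_a] += need[(cls, p)]
        for i, (cls, pp) in enumerate(ch_keys):
            if pp == p:
                row[n_a + n_f + i] = -1.0
        ub_rows.append(row)
        ub_b.append(res.period(p).labour_h)

    # Greening: every species pair capped at 95% of the land
    if greening:
        sp_rows = _species_area_rows(coeffs)
        cap = 0.95 * res.area_ha
        for sp_i, sp_j in itertools.combinations(sorted(sp_rows), 2):
            ub_rows.append(a_slice(sp_rows[sp_i] + sp_rows[sp_j]))
            ub_b.append(cap)

    # --- objective
    fees = np.array(
        [prices.contractor_fees.get(cls.value, 0.0) for cls, _ in ch_keys]
    )
    c_vec = np.zeros(n)
    if objective == "max_GM":
        c_vec[:n_a] = [-c.gm for c in coeffs]
        c_vec[n_a + n_f :] = fees
        sense = -1
    elif objective == "max_NE":
        c_vec[:n_a] = [-c.ne_mj for c in coeffs]
        sense = -1
    else:  # min_GHG
        c_vec[:n_a] = [c.ghg_kg for c in coeffs]
        sense = 1

    return FarmProgram(
        objective=objective,
        calib=calib,
        tillage_id=tillage_id,
        price_year=str(price_year),
        coeffs=coeffs,
        flows=flows,
        ch_keys=ch_keys,
        c=c_vec,
        A_ub=np.array(ub_rows),
        b_ub=np.array(ub_b),
        A_eq=np.array(eq_rows),
        b_eq=np.array(eq_b),
        sense=sense,
        greening=greening,
        options={
            "yield_multiplier": yield_multiplier,
            "herbicide_addon": herbicide_addon,
        },
    )


def apply_greening(program: FarmProgram) -> FarmProgram:
    """Return a copy of the programme with the Greening pairwise species
    caps added (idempotent if already applied)."""
    if program.greening:
        return program
    return build_program(
        program.calib,
        program.tillage_id,
        program.objective,
        program.price_year,
        greening=True,
        yield_multiplier=program.options.get("yield_multiplier", 1.0),
        herbicide_addon=program.options.get("herbicide_addon", 0.0),
    )


def _linprog(c, A_ub, b_ub, A_eq, b_eq):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
    )


def _diagnose_infeasibility(program: FarmProgram) -> str:
    if program.greening:
        relaxed = build_program(
            program.calib,
            program.tillage_id,
            program.objective,
            program.price_year,
            greening=False,
            yield_multiplier=program.options.get("yield_multiplier", 1.0),
            herbicide_addon=program.options.get("herbicide_addon", 0.0),
        )
        if _linprog(relaxed.c, relaxed.A_ub, relaxed.b_ub, relaxed.A_eq, relaxed.b_eq).status == 0:
            return "greening"
    # try with resource rows dropped (keep rotation + land + greening)
    n_res = len(program.ch_keys) * 2 + len(program.calib.resources.periods)
    A = program.A_ub[n_res:]
    b = program.b_ub[n_res:]
    r = _linprog(program.c, A if len(A) else None, b if len(b) else None,
                 program.A_eq, program.b_eq)
    if r.status == 0:
        return "resources"
    return "rotation/land"


def solve(program: FarmProgram, tie_break: bool = True) -> FarmSolution:
    """Solve the farm LP and report the plan with all three metrics.

    ``tie_break`` runs a secondary solve that, holding the objective at its
    optimum, prefers the lexicographically smallest activity index — a
    documented deterministic choice among alternate optimal vertices.
    """
    res = _linprog(program.c, program.A_ub, program.b_ub, program.A_eq, program.b_eq)
    if res.status == 2:
        group = _diagnose_infeasibility(program)
        raise InfeasibleProgramError(
            f"farm programme infeasible (binding constraint group: {group})"
        )
    if res.status == 3:
        raise UnboundedProgramError("farm programme is unbounded")
    if res.status != 0:
        raise RuntimeError(f"solver failure: {res.message}")
    x = res.x
    opt = float(program.c @ x)

    if tie_break:
        # pin the objective at its optimum and prefer the lexicographically
        # smallest activity mix among the alternate optimal vertices
        n_a = program.n_activities
        w = np.zeros(program.n_vars)
        w[:n_a] = np.arange(1, n_a + 1)
        A_eq2 = np.vstack([program.A_eq, program.c])
        b_eq2 = np.append(program.b_eq, opt)
        res2 = _linprog(w, program.A_ub, program.b_ub, A_eq2, b_eq2)
        if res2.status == 0:
            x = res2.x

    return _report(program, x)


def _report(program: FarmProgram, x: np.ndarray) -> FarmSolution:
    calib = program.calib
    prices = calib.prices(program.price_year)
    n_a, n_f = program.n_activities, len(program.flows)
    areas_vec = x[:n_a]

    # minimum-fee contracting given the chosen areas (re-solved so that the
    # fee report is well-defined under the energy/GHG objectives too)
    need = {}
    for cls, p in program.ch_keys:
        need[(cls, p)] = float(
            sum(
                a * c.hours.get((cls, p), 0.0)
                for a, c in zip(areas_vec, program.coeffs)
            )
        )
    ch = _min_fee_contracting(program, need)

    areas = {
        c.id: float(a) for c, a in zip(program.coeffs, areas_vec) if a > 1e-9
    }
    species_areas: dict[str, float] = {}
    for c, a in zip(program.coeffs, areas_vec):
        if a > 1e-9:
            sp = SPECIES_OF[c.activity.crop_id]
            species_areas[sp] = species_areas.get(sp, 0.0) + float(a)

    gm_acts = float(sum(a * c.gm for a, c in zip(areas_vec, program.coeffs)))
    hourly_fees = float(
        sum(
            ch[k] * prices.contractor_fees.get(k[0].value, 0.0)
            for k in program.ch_keys
        )
    )
    baling = float(
        sum(
            a * c.cost_components.get("baling_contract", 0.0)
            for a, c in zip(areas_vec, program.coeffs)
        )
    )
    own_hours = {
        k: max(0.0, need[k] - ch[k]) for k in program.ch_keys if need[k] > 1e-9
    }
    contractor_hours = {k: ch[k] for k in program.ch_keys if ch[k] > 1e-9}

    obj_value = float(program.c @ x) if program.sense == 1 else float(-(program.c @ x))
    return FarmSolution(
        objective=program.objective,
        tillage_id=program.tillage_id,
        price_year=program.price_year,
        areas=areas,
        species_areas=species_areas,
        gm=gm_acts - hourly_fees,
        ne_gj=float(sum(a * c.ne_mj for a, c in zip(areas_vec, program.coeffs))) / 1000.0,
        ghg_kg=float(sum(a * c.ghg_kg for a, c in zip(areas_vec, program.coeffs))),
        fuel_l=float(sum(a * c.fuel_l for a, c in zip(areas_vec, program.coeffs))),
        contractor_fees=hourly_fees + baling,
        own_hours=own_hours,
        contractor_hours=contractor_hours,
        output_t=float(sum(a * c.output_t for a, c in zip(areas_vec, program.coeffs))),
        output_kcal=float(
            sum(a * c.output_kcal for a, c in zip(areas_vec, program.coeffs))
        ),
        objective_value=obj_value,
        flows={
            fk: float(v)
            for fk, v in zip(program.flows, x[n_a : n_a + n_f])
            if v > 1e-9
        },
    )


def _min_fee_contracting(
    program: FarmProgram, need: dict[tuple[MachineClass, str], float]
) -> dict[tuple[MachineClass, str], float]:
    """Smallest-fee contractor-hour allocation for fixed activity areas."""
    resr = program.calib.resources
    prices = program.calib.prices(program.price_year)
    keys = program.ch_keys
    nk = len(keys)
    c = np.array([prices.contractor_fees.get(cls.value, 0.0) for cls, _ in keys])
    rows, b = [], []
    for i, (cls, p) in enumerate(keys):
        row = np.zeros(nk)
        row[i] = -1.0  # need - ch <= cap
        rows.append(row)
        b.append(resr.period(p).machine_h.get(cls.value, 0.0) - need[(cls, p)])
        row2 = np.zeros(nk)
        row2[i] = 1.0  # ch <= need
        rows.append(row2)
        b.append(need[(cls, p)])
    for p in resr.period_ids:
        row = np.zeros(nk)
        tot = 0.0
        for i, (cls, pp) in enumerate(keys):
            if pp == p:
                row[i] = -1.0
                tot += need[(cls, pp)]
        rows.append(row)
        b.append(resr.period(p).labour_h - tot)
    r = linprog(c, A_ub=np.array(rows), b_ub=np.array(b), bounds=(0, None), method="highs")
    if r.status != 0:
        raise RuntimeError("contracting sub-problem failed; inconsistent solution")
    return {k: float(max(0.0, v)) for k, v in zip(keys, r.x)}
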