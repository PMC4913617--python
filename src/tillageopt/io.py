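"""Reading and writing calibration bundles.

A calibration lives in a directory holding one master YAML file plus CSV
side-tables mirroring the published parameter tables column-for-column
(tillage operations, pesticide programmes, crop prices, contractor fees,
machines, work periods) and a provenance sidecar tagging every parameter
as published or placeholder.  ``write_calibration`` then
``load_calibration`` round-trips a bundle losslessly.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from .domain import (
    Calibration,
    Crop,
    EmissionFactors,
    EnergyFactors,
    FarmResources,
    FieldOperation,
    Machine,
    MachineClass,
    PesticideCategory,
    PriceSet,
    ProvenanceRecord,
    SPECIES,
    TillageSystem,
    ValidationError,
    WorkPeriod,
)

MASTER = "calibration.yaml"

_CROP_COLS = [
    "id", "category", "season", "establishment_period", "harvest_period",
    "grain_yield", "straw_yield", "grain_energy_gj_t", "straw_energy_gj_t",
    "kcal_per_kg", "n_rate", "p_rate", "k_rate", "seed_cost",
    "seed_energy_mj", "drying_fuel_l_t",
]
_MACHINE_COLS = [
    "id", "machine_class", "weight_kg", "price_gbp", "lifespan_h",
    "fuel_l_h", "spares_rate", "insurance_rate", "high_usage_cost",
    "depreciation_schedule",
]


def _sched_str(sched: list[tuple[float, float]]) -> str:
    return ";".join(f"{h}:{r}" for h, r in sched)


def _sched_parse(s: str) -> list[tuple[float, float]]:
    if not s or (isinstance(s, float) and pd.isna(s)):
        return []
    out = []
    for part in str(s).split(";"):
        h, r = part.split(":")
        out.append((float(h), float(r)))
    return out


def _op_row(op: FieldOperation, **extra) -> dict:
    row = {
        "implement_id": op.implement_id,
        "power_class": op.power_class.value,
        "work_rate_min_ha": op.work_rate_min_ha,
        "timing": op.timing,
        "straw_only": op.straw_only,
        "sprays_as_passes": op.sprays_as_passes,
        **extra,
    }
    for sp in SPECIES:
        row[sp] = op.passes.get(sp, "")
    return row


def _op_from_row(row: pd.Series) -> FieldOperation:
    passes = {}
    for sp in SPECIES:
        v = row.get(sp, "")
        if v != "" and not pd.isna(v):
            passes[sp] = int(v)
    return FieldOperation(
        implement_id=row["implement_id"],
        power_class=MachineClass(row["power_class"]),
        work_rate_min_ha=float(row["work_rate_min_ha"]),
        timing=str(row["timing"]),
        passes=passes,
        straw_only=bool(row.get("straw_only", False)),
        sprays_as_passes=bool(row.get("sprays_as_passes", False)),
    )


def write_calibration(calib: Calibration, path: str | os.PathLike) -> Path:
    """Write a bundle to a directory; returns the master file path."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    years = sorted(calib.price_sets)

    pd.DataFrame(
        [{c: getattr(crop, c) for c in _CROP_COLS} for crop in calib.crops.values()]
    ).to_csv(d / "crops.csv", index=False)

    pd.DataFrame(
        [
            {
                **{c: getattr(m, c) for c in _MACHINE_COLS[:-1]},
                "machine_class": m.machine_class.value,
                "depreciation_schedule": _sched_str(m.depreciation_schedule),
            }
            for m in calib.machines.values()
        ]
    )[_MACHINE_COLS].to_csv(d / "machines.csv", index=False)

    till_rows = []
    for ts in calib.tillage_systems.values():
        for op in ts.operations:
            till_rows.append(_op_row(op, system=ts.id))
    pd.DataFrame(till_rows).to_csv(d / "tillage_operations.csv", index=False)

    pd.DataFrame([_op_row(op) for op in calib.shared_operations]).to_csv(
        d / "shared_operations.csv", index=False
    )

    pest_rows = []
    for crop in calib.crops.values():
        for cat in crop.pesticide_program:
            row = {"crop": crop.id, "category": cat.name, "sprays": cat.sprays}
            for y in years:
                row[f"cost_{y}"] = calib.price_sets[y].pesticide_costs[crop.id][cat.name]
            pest_rows.append(row)
    pd.DataFrame(pest_rows).to_csv(d / "pesticides.csv", index=False)

    price_rows = []
    ps0 = calib.price_sets[years[0]]
    for product, table in (("grain", "grain_prices"), ("straw", "straw_prices")):
        for sp in getattr(ps0, table):
            row = {"species": sp, "product": product}
            for y in years:
                row[f"price_{y}"] = getattr(calib.price_sets[y], table)[sp]
            price_rows.append(row)
    pd.DataFrame(price_rows).to_csv(d / "crop_prices.csv", index=False)

    fee_rows = []
    for cls in ps0.contractor_fees:
        row = {"machine_class": cls}
        for y in years:
            row[f"fee_{y}"] = calib.price_sets[y].contractor_fees[cls]
        fee_rows.append(row)
    pd.DataFrame(fee_rows).to_csv(d / "contractor_fees.csv", index=False)

    period_rows = []
    for p in calib.resources.periods:
        period_rows.append({"id": p.id, "labour_h": p.labour_h, **p.machine_h})
    pd.DataFrame(period_rows).to_csv(d / "work_periods.csv", index=False)

    pd.DataFrame([r.model_dump() for r in calib.provenance]).to_csv(
        d / "provenance.csv", index=False
    )

    master = {
        "emission_factors": calib.emission_factors.model_dump(),
        "energy_factors": calib.energy_factors.model_dump(),
        "resources": {
            "area_ha": calib.resources.area_ha,
            "interest_rate": calib.resources.interest_rate,
            "spring_period": calib.resources.spring_period,
        },
        "n_response": {float(k): float(v) for k, v in calib.n_response.items()},
        "wosr_broadcast": {
            tid: ts.wosr_broadcast for tid, ts in calib.tillage_systems.items()
        },
        "price_scalars": {
            y: {
                f: getattr(calib.price_sets[y], f)
                for f in ("n_price_kg", "p_price_kg", "k_price_kg",
                          "fuel_price_l", "labour_wage", "overhead_frac",
                          "labour_surcharge")
            }
            for y in years
        },
    }
    with open(d / MASTER, "w") as fh:
        yaml.safe_dump(master, fh, sort_keys=False)
    return d / MASTER


def load_calibration(path: str | os.PathLike) -> Calibration:
    """Load and validate a calibration bundle from a directory (or its
    master YAML file).  Any dangling cross-reference, unknown id or
    invariant violation raises :class:`ValidationError` naming the field."""
    p = Path(path)
    d = p.parent if p.is_file() else p
    master_path = d / MASTER
    if not master_path.exists():
        raise FileNotFoundError(f"no {MASTER} in {d}")
    with open(master_path) as fh:
        master = yaml.safe_load(fh)

    def read(name):
        f = d / name
        if not f.exists():
            raise ValidationError(f"missing calibration table {name}")
        return pd.read_csv(f)

    crops_df = read("crops.csv")
    pest_df = read("pesticides.csv")
    years = sorted(
        c.removeprefix("cost_") for c in pest_df.columns if c.startswith("cost_")
    )

    try:
        crops = {}
        for _, row in crops_df.iterrows():
            prog = [
                PesticideCategory(name=r["category"], sprays=int(r["sprays"]))
                for _, r in pest_df[pest_df["crop"] == row["id"]].iterrows()
            ]
            crops[row["id"]] = Crop(
                **{c: row[c] for c in _CROP_COLS}, pesticide_program=prog
            )

        machines = {}
        for _, row in read("machines.csv").iterrows():
            machines[row["id"]] = Machine(
                id=row["id"],
                machine_class=MachineClass(row["machine_class"]),
                weight_kg=float(row["weight_kg"]),
                price_gbp=float(row["price_gbp"]),
                lifespan_h=float(row["lifespan_h"]),
                fuel_l_h=float(row["fuel_l_h"]),
                spares_rate=float(row["spares_rate"]),
                insurance_rate=float(row["insurance_rate"]),
                high_usage_cost=float(row["high_usage_cost"]),
                depreciation_schedule=_sched_parse(row["depreciation_schedule"]),
            )

        till_df = read("tillage_operations.csv")
        broadcast = master.get("wosr_broadcast", {})
        tillage_systems = {}
        for tid, grp in till_df.groupby("system", sort=False):
            tillage_systems[tid] = TillageSystem(
                id=tid,
                operations=[_op_from_row(r) for _, r in grp.iterrows()],
                wosr_broadcast=bool(broadcast.get(tid, False)),
            )

        shared_operations = [
            _op_from_row(r) for _, r in read("shared_operations.csv").iterrows()
        ]

        periods = []
        pdf = read("work_periods.csv")
        cls_cols = [c for c in pdf.columns if c not in ("id", "labour_h")]
        for _, row in pdf.iterrows():
            mh = {
                c: float(row[c]) for c in cls_cols if not pd.isna(row[c])
            }
            periods.append(
                WorkPeriod(id=row["id"], labour_h=float(row["labour_h"]), machine_h=mh)
            )
        res_cfg = master["resources"]
        resources = FarmResources(
            area_ha=float(res_cfg["area_ha"]),
            interest_rate=float(res_cfg["interest_rate"]),
            spring_period=res_cfg["spring_period"],
            periods=periods,
        )

        prices_df = read("crop_prices.csv")
        fees_df = read("contractor_fees.csv")
        price_sets = {}
        for y in years:
            grain, straw = {}, {}
            for _, row in prices_df.iterrows():
                tgt = grain if row["product"] == "grain" else straw
                tgt[row["species"]] = float(row[f"price_{y}"])
            pest_costs: dict[str, dict[str, float]] = {}
            for _, row in pest_df.iterrows():
                pest_costs.setdefault(row["crop"], {})[row["category"]] = float(
                    row[f"cost_{y}"]
                )
            fees = {
                row["machine_class"]: float(row[f"fee_{y}"])
                for _, row in fees_df.iterrows()
            }
            price_sets[y] = PriceSet(
                year=y,
                grain_prices=grain,
                straw_prices=straw,
                pesticide_costs=pest_costs,
                contractor_fees=fees,
                **master["price_scalars"][y],
            )

        prov_path = d / "provenance.csv"
        provenance = []
        if prov_path.exists():
            prov_df = pd.read_csv(prov_path).fillna("")
            provenance = [
                ProvenanceRecord(**row) for row in prov_df.to_dict("records")
            ]

        return Calibration(
            crops=crops,
            machines=machines,
            tillage_systems=tillage_systems,
            shared_operations=shared_operations,
            emission_factors=EmissionFactors(**master["emission_factors"]),
            energy_factors=EnergyFactors(**master["energy_factors"]),
            resources=resources,
            price_sets=price_sets,
            n_response={float(k): float(v) for k, v in master["n_response"].items()},
            provenance=provenance,
        )
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"invalid calibration bundle: {exc}") from exc


def default_calibration() -> Calibration:
    """The calibration shipped with the package."""
    data_dir = Path(__file__).parent / "data"
    return load_calibration(data_dir)
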