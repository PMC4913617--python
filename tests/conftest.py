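"""Shared fixtures: the paperlike calibration, pre-solved profit plans for
all six tillage systems, and reduced "toy" farms with relaxed resources
for oracle comparisons."""

from __future__ import annotations

import pytest

import tillageopt as t
from tillageopt.domain import Calibration

TILLAGE_IDS = ("CT", "RP", "DRT", "SRT1", "SRT2", "ZT")
FULL_RT = ("DRT", "SRT1", "SRT2")


@pytest.fixture(scope="session")
def calib() -> Calibration:
    return t.paperlike_calibration()


@pytest.fixture(scope="session")
def gm_solutions(calib):
    """Profit-maximised plans for every tillage system (2011 prices)."""
    return {
        tid: t.solve(t.build_program(calib, tid, "max_GM"))
        for tid in TILLAGE_IDS
    }


@pytest.fixture(scope="session")
def nm_reports(calib, gm_solutions):
    out = {}
    for tid, sol in gm_solutions.items():
        comp = t.size_complement(sol, calib, tid)
        out[tid] = (
            comp,
            t.net_margin(sol, comp, calib.prices("2011"), calib.resources),
        )
    return out


def make_toy(
    base: Calibration,
    crop_ids: tuple[str, ...],
    relax_resources: bool = True,
) -> Calibration:
    """A farm restricted to a subset of crop variants; resource limits are
    relaxed so rotation and land are the only binding constraints."""
    toy = base.model_copy(deep=True)
    toy.crops = {cid: toy.crops[cid] for cid in crop_ids}
    if relax_resources:
        for p in toy.resources.periods:
            p.labour_h = 1e6
            p.machine_h = {cls: 1e6 for cls in p.machine_h}
            for cls in ("small_tractor", "medium_tractor", "large_tractor", "combine"):
                p.machine_h.setdefault(cls, 1e6)
    return Calibration.model_validate(toy.model_dump())


@pytest.fixture(scope="session")
def single_crop_calib(calib):
    """Continuous wheat only: the rotation self-loop pins the crop mix, so
    farm totals are affine in any uniform yield multiplier."""
    return make_toy(calib, ("WWc",))


@pytest.fixture(scope="session")
def pair_calib(calib):
    """First wheat + oilseed rape: rotation forces an exact 50/50 split."""
    return make_toy(calib, ("WW1", "WOSR"))
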