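# tillageopt

Bio-economic modelling of reduced tillage on UK arable farms.

Reduced and zero tillage replace the plough with fewer, faster, shallower
passes — or none at all. That saves fuel, labour, machinery and
contracting costs, but can cost yield and demand more herbicide. Whether
the trade is worth making is a *system* question: the answer depends on
the whole rotation, the farm's labour calendar, who owns which machines,
and what the policy rules allow. `tillageopt` answers it the way farm
economists do, with a farm-level optimisation model:

* **per-hectare accounting** for every crop activity (crop variant ×
  straw fate × N level): gross margin (GM), net energy (NE) and GHG
  emissions, with soil N₂O as
  `(EF·N_applied + background) · 44/28 · GWP` and machinery burdens
  allocated by hours at `weight · steel factor / lifespan`;
* a **linear programme** choosing the crop mix on 400 ha to maximise GM,
  maximise NE or minimise GHG under steady-state rotation constraints
  (break crops only after cereals, first → second → continuous wheat),
  per-period labour/machine balances with contractor hire at a fee, and
  optional CAP-Greening caps (any two species ≤ 95% of the land);
* a **net-margin layer**: the machinery complement implied by the plan,
  with usage-dependent straight-line depreciation (15%/yr at 500 h to
  27%/yr at 1500 h for a medium tractor), spares, insurance, interest
  and labour;
* a **scenario engine**: tillage-system comparisons under 2011 and 2014
  prices, black-grass herbicide add-ons, spring-barley selection sweeps,
  CAP-Greening runs, and breakeven yield-penalty search by bisection
  over the re-optimised programme, including the extra land (and its
  emissions) needed to hold food output constant.

It is intended for agricultural-systems researchers and modellers who
want a transparent, fully testable implementation of this class of
farm model: every farm-level figure decomposes into an auditable
per-activity coefficient table.

## Worked example

```python
import tillageopt as t

calib = t.default_calibration()          # shipped, provenance-tagged bundle
sol   = t.solve(t.build_program(calib, "ZT", "max_GM"))
comp  = t.size_complement(sol, calib, "ZT")
nm    = t.net_margin(sol, comp, calib.prices("2011"), calib.resources)
print(f"GM {sol.gm:,.0f} GBP, NE {sol.ne_gj:,.0f} GJ, "
      f"GHG {sol.ghg_kg:,.0f} kg CO2-eq, NM {nm.nm:,.0f} GBP")
```

prints

```
GM 365,132 GBP, NE 38,151 GJ, GHG 1,335,280 kg CO2-eq, NM 288,280 GBP
```

— the profit-maximal zero-tillage plan (200 ha first wheat after 200 ha
oilseed rape, straw baled, 75% N) earns a farm gross margin of
GBP 365k; after usage-adjusted machinery costs (no plough, no power
harrow, no large tractor) and labour, the net margin is GBP 288k.
The same comparison across all six tillage systems, via the CLI:

```sh
$ tillageopt net-margin
              CT     RP    DRT   SRT1   SRT2     ZT
nm_per_ha  518.0  558.0  634.0  675.0  702.0  721.0
```

Net margin per hectare rises monotonically as tillage intensity falls:
conventional ploughing is the most expensive way to establish these
crops, rotational ploughing recovers part of the saving, and direct
drilling keeps the most. Other subcommands: `tillageopt optimize`,
`sweep-yield` (breakeven yield penalty), `sb-sweep`, `scenario-matrix`.
All outputs are CSV/JSON with a run log carrying the calibration hash.

Because the predecessor model's calibration (yields, fuel rates, energy
contents, labour calendar) is not published, the shipped bundle fills
those slots with documented placeholders (tagged in
`src/tillageopt/data/provenance.csv`); absolute farm totals are
therefore properties of this fixture, while the table-level arithmetic,
accounting identities and qualitative system orderings are reproduced
exactly. See `docs/methods.md`.

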