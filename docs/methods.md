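# Methods

## The model

`tillageopt` is a single-year bio-economic model of a 400 ha UK arable
farm choosing a crop mix under one of six tillage systems of decreasing
intensity:

| id | system | cultivation before drilling |
|----|--------|------------------------------|
| CT | conventional | plough (70 min/ha) + 2 passes of a power harrow (67 min/ha each) |
| RP | rotational ploughing | CT before cereals, 2 disc passes before break crops |
| DRT | deep reduced tillage | 2 passes of a one-pass cultivator (24 min/ha, large tractor) |
| SRT1 | shallow reduced tillage | 2 passes of a medium disc harrow (42 min/ha) |
| SRT2 | shallow reduced tillage | 2 passes of a spring-tine harrow (23 min/ha) |
| ZT | zero tillage | direct drilling only (43 min/ha) |

Under RP/DRT/SRT1/SRT2 oilseed rape seed is broadcast with the tillage
passes, so WOSR incurs no drill pass; under ZT the drill is required.

### Activities

A crop *activity* is a variant × straw fate × nitrogen level:

* variants — first, second and continuous winter wheat (WW1/WW2/WWc,
  sharing one "wheat" species for prices and policy counts), winter and
  spring barley (WB/SB), winter oilseed rape (WOSR), winter field beans
  (WFB);
* straw (cereals only) — baled and sold (SR) or incorporated;
* N level — 50%, 75% or 100% of the recommended rate, with a concave
  yield response (multipliers 0.90 / 0.99 / 1.00) so that 75% N is
  profit-optimal, full N maximises raw yield, and half N minimises
  emissions.

For each activity three per-hectare metrics are assembled from explicit
components (retained as an audit table):

* **GM** (GBP/ha) = grain + baled-straw revenue − fertiliser − crop
  protection − seed − fuel (field operations + grain drying) − fixed
  swather/baler contracting. Grain drying (L/t of grain) is the only
  yield-proportional cost; everything else is fixed per hectare, which is
  why farm GM is exactly affine in a uniform yield multiplier.
* **NE** (MJ/ha) = energy in grain (+ baled straw) − energy embedded in
  fertiliser, pesticides, seed, fuel and machinery.
* **GHG** (kg CO₂-eq/ha) = input manufacture + fuel combustion +
  machinery embedded + soil N₂O, with soil N₂O =
  (0.016 × applied N + 1.4) × 44/28 × GWP(N₂O). The default GWP is 298
  (AR4 100-year value); it is configurable because reported values for
  this conversion vary between inventories.

Machinery embedded burdens are allocated by hours of use:
`weight × per-kg steel factor / 3000 h lifespan`, for the implement and
its power unit, whether the farm or a contractor operates them — this
keeps NE and GHG independent of ownership. The steel energy factor is
23 MJ/kg: the tabulated hourly values (e.g. a 7350 kg cultivator →
56.35 MJ/h) are arithmetically consistent only with MJ/kg, although the
printed unit is GJ/kg. The tabulated hourly *emission* values
(3.83/0.90/1.81 kg CO₂-eq/h) are not mutually consistent with
`weight × 1.56 / 3000` under any single rounding rule (the formula gives
3.82 / 0.89 / 1.82); this package always computes from the formula rather
than hard-coding those cells.

### The farm programme

A linear programme over activity areas, rotation flows and contractor
hours:

* land balance: Σ areas = 400 ha (equality — all land is cropped);
* steady-state rotation: a flow variable carries hectares from each
  predecessor to each permitted successor and every crop's area equals
  both its inflow and outflow. Permitted transitions: break → {WW1, WB,
  SB}; any cereal → {WB, SB, WOSR, WFB}; WW1 → WW2 → WWc, with WWc
  self-succeeding (continuous wheat). Break after break is forbidden.
  The network form is a convention — the predecessor model's exact
  constraint list is not published — chosen because it reproduces every
  published crop-mix pattern (e.g. first wheat area = break area in the
  profit-maximal mixes; a break crop splitting between first wheat and
  barley under 2014 prices).
* resources: the year is split into five work periods (early harvest,
  late harvest, September, October, spring) with labour hours and own
  machine hours per class in each. Requirements above own capacity are
  met by unbounded contractor-hour variables priced at the class fee
  (fees cover machine and operator, so contracted hours relieve both
  balances; contracted hours cannot exceed the hours actually required).
  Swathing and baling are always contracted at a fixed per-hectare fee.
* Greening (optional): every unordered species pair ≤ 95% of the land
  (380 ha). With land fixed at 400 ha this simultaneously forces at
  least three species and a third-largest area of ≥ 20 ha, without
  integer variables.

Objectives: maximise GM (net of hourly contracting fees), maximise NE,
or minimise GHG. Solved with HiGHS through `scipy.optimize.linprog`.
Among alternate optima a secondary solve pins the objective at its
optimum (as an equality row) and minimises an index-weighted area sum,
preferring the lexicographically smallest activity mix — a documented,
deterministic tie-break. For the energy/emission objectives contractor
fees do not enter the objective, so the reported fee bill is defined by
a minimum-fee re-solve of the contracting sub-problem at fixed areas.

### Net margin

NM = GM − machinery ownership costs − labour. The machinery complement
is exactly the set of machines performing own-farm work in the plan
(contracted slots are excluded pro-rata). Per machine and year:

* depreciation: straight-line, rate interpolated from (annual hours,
  rate) anchors and clamped outside them — a medium tractor runs from
  15%/yr at 500 h to 27%/yr at 1500 h; anchors for other machines are
  calibration placeholders;
* spares & repairs and insurance: flat fractions of purchase price
  (handbook-style placeholders);
* interest: 3% on average invested capital (price/2); the base is a
  deliberate design choice — only the 3% rate is given externally.

Labour is own machine-hours × wage. 2011 contractor fees are taken from
the fee table; 2014 fees are constructed as
`hourly cost at high usage × 1.25 + wage × 1.35` (labour component
GBP 13.76/h at the 2014 wage of GBP 10.19/h); the shipped high-usage
costs are back-derived so the construction reproduces the 2014 fee
table, making the construction testable.

### Scenario engine

* **Yield-penalty thresholds** — bisection on a uniform penalty p,
  re-optimising the LP at each step, until the chosen metric (GM, NE,
  GHG per tonne of output, or total GHG at constant calorie production)
  equals the conventional-tillage zero-penalty baseline. The optimised
  GM is a maximum of affine functions of p, hence convex,
  piecewise-linear and nonincreasing, which the bisection exploits; a
  metric with no sign change on [0, 1] is reported as "no threshold".
  GM- and GHG-based metrics re-optimise the profit objective (the
  farmer's mix); the NE metric re-optimises net energy.
* **Land compensation** — extra land fraction = baseline output /
  penalised output − 1, in tonnes and in calories, using the penalised
  solution's own mix; extra-land GHG = penalised per-ha emissions ×
  extra hectares (calorie-equalising basis).
* **Weed control** — a biennial black-grass herbicide programme of
  GBP 85/ha is annualised by halving in this steady-state single-year
  model; the extreme variant charges the full GBP 85/ha/yr. The extra
  spraying pass adds GBP 4.81/ha/yr of machinery/fuel/labour cost on the
  net-margin side, charged per application year (a configurable choice —
  whether it applies per application or per year is ambiguous in the
  source).
* **Spring-barley sweep** — penalties applied to every crop except SB;
  reports the optimised SB area, its entry threshold and the penalty at
  which SB exceeds 100 ha.
* **Scenario matrix** — every year × objective × Greening × tillage
  combination, with tabular writers and pairwise deltas rounded in the
  reporting style of the source (integer percents, whole GBP/ha).

## The synthetic calibration

The shipped bundle merges all published values (work-rates, pass
matrices, implement weights, steel factors, pesticide programmes and
costs, crop/straw prices for 2011 and 2014, contractor fees, N₂O
factors, depreciation anchors, interest, farm area, fee construction)
with placeholders for everything only the unpublished predecessor
calibration carries: crop yields and energy/calorie contents, fertiliser
rates, seed costs, machine prices and fuel rates, input manufacture
factors, the N-yield response, and the work-period structure. Every
parameter is tagged `paper` (with a citation note) or `placeholder` in a
provenance sidecar, and the tagging is complete by construction.

Placeholders are anchored to UK farm-management magnitudes (winter wheat
8 t/ha first-wheat yield, red diesel ≈ GBP 0.645/L, medium tractor
GBP 58k) and were fixed once so that the fixture reproduces the
qualitative structure of the published results:

* conventional-tillage profit maximisation selects a three-way
  WW/WB/WOSR mix (autumn labour scarcity plus contracting costs pull
  winter barley, with its September establishment and early harvest,
  into the rotation);
* GM and NM rise monotonically CT → RP → {DRT, SRT1, SRT2} → ZT, fuel
  falls along the same ordering, and DRT matches SRT1 on GM but trails
  it on NM (the large tractor);
* spring barley is never selected at baseline and enters only when all
  other crops are penalised by more than ~17%, first on a small area,
  with all four of WW, WB, WOSR and SB present at a 20% penalty.

The seeded random generator perturbs yields, prices, work-rates, fuel
rates and labour within documented uniform bands (±10–20%) around the
paperlike values, leaving structural tables intact, so every draw is a
valid, feasible farm; the same seed gives a bit-identical bundle.

### What the fixture does and does not show

The generator emulates the *structure* of the original study conditions,
not its unpublished numbers. Passing tests therefore demonstrate that
the accounting identities, the LP mechanics, the policy constraints and
the scenario logic are correct, and that the qualitative economics of
reduced tillage (cost and fuel savings, contracting relief, machinery
shedding) emerge from those mechanics. Absolute farm totals, threshold
penalties (here ≈ 8.8% for the ZT gross-margin breakeven) and crop-mix
areas are calibration-dependent and are not comparable to the published
absolute values. Two known behavioural divergences on the shipped
fixture: the emission-minimal mix uses spring barley (its low N rate
beats the 50%-N wheat here) where the source reports wheat at 50% N with
beans; and the GHG-per-tonne metric of ZT starts above the CT baseline
(the mix shift toward low-tonnage oilseed rape outweighs the machinery
saving), so that threshold is reported as absent on this fixture — it
exists whenever the crop mix is pinned, which is how it is tested.

## Numerical choices

* Solver: HiGHS (dual simplex) via scipy; vertex solutions; land balance
  tolerance 1e-6 ha in all assertions.
* Bisection: tolerance relative to the baseline magnitude (default
  1e-3), at most 60 iterations; per-output metrics at a total penalty
  (zero output) are treated as +∞.
* Degenerate inputs: zero-weight machines carry no embedded burden;
  empty pesticide programmes cost nothing; an empty depreciation
  schedule, a zero percent-change base, negative N and unknown
  crops/objectives raise immediately with the offending field named.
* Reporting: money to the penny, energy in GJ, deltas rounded to integer
  percents / whole GBP per hectare.

## Problem sizes

The default farm programme has 34 activities, 27 rotation flows and 20
contractor-hour variables — solves are milliseconds, so the test suite
re-optimises freely (grid scans use 0.1% penalty steps; the generator
feasibility sweep covers 100 seeds).

## Limitations

No within-season dynamics, stochastic yields or pest-population model;
no soil-carbon sequestration accounting; no N-fertiliser × tillage
interaction; no multi-year machinery investment (the complement is a
post-processing step, not an integer programme); no Basic Payment
subsidy (decoupled). Units are fixed by convention — there is no units
library.
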