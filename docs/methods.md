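# Methods

## Model structure and assumptions

The coal-mining area is modelled as five independent pollution subsystems —
atmospheric, solid waste, water resource, vegetation cover and land
reclamation — each a single stock fed by constant monthly production and
drained by a treatment flow.  Independence is a modelling assumption, not a
physical claim: each subsystem's quality is determined only by its own stock,
with no cross-subsystem pollution transport.  The package exploits it
structurally (the assembled five-stock model is the exact union of the five
fragments, and the tests assert bit-identical series either way) but it also
bounds what the model can say: interactions such as gangue leaching degrading
both soil and water are represented only as the same production constant
appearing in two subsystems.

Integration is fixed-step explicit Euler with a one-month step over a
24-month horizon (`initial_time = 0`, `final_time = 24`, `dt = 1`), the
standard DYNAMO/Vensim level–rate scheme.  The published level equations as
printed update a level from the previous *rate*, which is dimensionally
inconsistent and cannot produce the saturating trajectories the accompanying
figures show; the engine implements the canonical form
`stock(t+dt) = stock(t) + dt·(inflow − outflow)` with all rates evaluated
from the start-of-step state.  The expression language is deliberately
minimal — `+ − × ÷` and parentheses — because the model uses nothing else;
there are no conditionals, lookups or delays, and no higher-order
integrators.

## Parameters

All defaults are embedded in `MineParams` so an empty configuration
reproduces the reference model.

| parameter | default | unit | role |
|---|---|---|---|
| `environmental_investment` | 50 | ten thousand yuan / month | the fixed budget `E` |
| `dust`, `waste_gas` | 3310, 1514 | m²/month | air production (4824 total) |
| `coal_gangue`, `living_garbage`, `boiler_ash` | 8750, 0, 298 | m²/month | solid production (9048) |
| `coal_gangue`, `life_wastewater`, `mine_water`, `gangue_leaching` | 8750, 980, 5392, 73 | m²/month | water production (15195) |
| `construction_square`, `waste_rock_pile`, `open_pit`, `road` | 30000, 9833, 1500, 80 | m²/month | vegetation destruction (4.1413 after unit harmonization) |
| `land_subsidence`, `land_to_dig` | 4400, 8800 | m²/month | land damage (1.32 harmonized) |
| `total_vegetation_area` | 2645.2 | 10⁴ m² | greening-rate denominator |
| initial stocks | 300 / 25.6 / 35 / 275 / 450 | m² (air, solid, water); 10⁴ m² (vegetation, land) | month-0 pollution |

Notes on the defaults:

- **Living garbage** appears in the solid-waste production equation but has
  no tabulated value; it defaults to 0 and is user-overridable.
- **NO2/SO2/CO** have no individual values; the aggregate `waste_gas` is
  used, and the three components are optional parameters that replace the
  aggregate when all three are supplied.
- **The budget** is treated as a constant per-month quantity for the whole
  horizon; its period is not stated in the source material, and since the
  technical factor divides investment by the same budget, the choice only
  matters for interpretation, not dynamics.
- **Units are inert labels.**  The source tabulates air/solid/water
  pollution stocks in m², which is taken at face value as an abstract
  pollution magnitude; no dimensional analysis is attempted.

## Structural switches

`removal_basis` (default `stock`): the printed treatment-rate equations are
inconsistent — air drains proportionally to the *stock* while solid waste
and water drain proportionally to *production*.  The default applies the
stock-proportional form uniformly, which yields the saturating
`P/p`-equilibrium dynamics the reference figures describe; `literal` follows
each printed equation verbatim (solid/water then accumulate the untreated
fraction of production linearly, with the stock never drawn down).  Both are
first-class and tested.

`unit_harmonization` (default on): vegetation/land production constants are
printed in m² while those stocks are in 10⁴ m².  Harmonization divides the
production sums by 10⁴ (4.1413 and 1.32 per month); without it the
vegetation stock is swamped by a pure unit artifact within one month.

## Quality assessment — a documented reconstruction

The reference model aggregates quality per subsystem, but its exact
per-subsystem formula is not available; this package defines

    q_i(t) = (B_i(t) − S_i(t)) / B_i(t)

against the zero-allocation baseline `B_i`, chosen because it is
scale-invariant across subsystems whose magnitudes differ by four orders,
maps "no treatment" to exactly 0, and is bounded in [0, 1] whenever removal
is nonnegative.  The overall score is the unweighted mean of the five.

This choice is load-bearing for one result.  Per-subsystem conclusions are
formula-independent (lower stock ⇔ higher quality, and every boosted case
dominates its own subsystem at every month).  The *overall* ranking is not:
under this reconstruction the even split (case 6, Q(24) = 0.8604) ranks
first and the vegetation-boosted case 4 (0.8240) fourth, because the
fast-growing air/solid/water baselines dominate the mean, whereas the source
reports case 4 first and case 6 second.  The ranking report therefore
*records* whether the case-4-then-case-6 ordering holds
(`RankingReport.case4_then_case6`) alongside the active options rather than
asserting it.  Ranking can be read at the final month (default) or as the
mean over the horizon (`statistic="mean"`); both orderings are reported by
the CLI via `--statistic`.

## Causal loop diagram

The diagram is reconstructed from the ten published loop listings as a
15-node signed digraph.  The listings contradict themselves on three edges
(cost→revenue, solid-investment→solid-index,
vegetation-investment→greening-rate each appear with both polarities); the
fixture uses the unique semantically consistent sign table — investment
raises quality-type indicators and lowers pollution indices, quality raises
eco-quality and lowers control cost, pollution indices do the opposite, cost
lowers revenue, revenue raises GDP, GDP raises the budget, eco-quality
lowers the budget — under which the five GDP–revenue loops are reinforcing
and the five eco-quality–budget loops balancing, matching the narrative
classification.  Only edges recoverable from the printed loops are included.
The economic closure (GDP, revenue, cost) exists *only* as this signed
graph; it is never simulated.

Loop enumeration uses Johnson's algorithm (`networkx.simple_cycles`); loops
are reported in canonical rotation (lexicographically smallest node first)
in sorted order, and the tests check the enumeration against an independent
brute-force path-growing oracle on the fixture and on random graphs.

## Sensitivity analysis

`oat_sensitivity` varies one subsystem's proportion across a grid while the
other four are held at a reference (default 0.15, capped at `(1 − p)/4` so
the allocation never exceeds the budget).  Because the subsystems are
independent, the reference value provably has no effect on the reported
subsystem's trajectory; the cap keeps every simulated policy a valid
allocation.  Final stock is strictly decreasing, and final quality strictly
increasing, in the subsystem's own proportion — a property the tests verify
on the grid 0.05…0.5 for all five subsystems.

## Numerical choices and degenerate inputs

- All arithmetic is plain float64; no tolerances are needed in the engine
  itself (it is exact recursion), and determinism is bit-level.
- The chained technical factor `(π·E)/E` is computed as written and checked
  against `π` to 1e-12 at every call.
- Ranking ties break toward the lower case id.
- Division by zero inside an expression raises an evaluation error naming
  the variable and the time step; quality assessment refuses a baseline
  stock that is not strictly positive (impossible with the default
  parameters, whose baselines are positive and nondecreasing).
- `validate_model` never raises: malformed expressions, dangling names,
  duplicate names and auxiliary cycles each yield one diagnostic.

## Problem sizes

The full scenario experiment is 7 simulations of a 5-stock model over 24
monthly steps; the whole test suite, including the property-based tests and
the brute-force cycle oracle on random 8-node graphs, runs in a few seconds.

## Known limitations

- Independence excludes cross-subsystem coupling and any economic feedback;
  the budget never responds to quality.
- Production is constant: no seasonality, no production growth or decline,
  no stochasticity.
- The quality formula is a reconstruction (above); conclusions about the
  *overall* case ordering should be read conditional on it.
- Euler with `dt = 1` at removal fractions near 1 is at the edge of
  stability of the explicit scheme (`p = 1` empties and refills the stock
  exactly each month); fractions above 1 are excluded by validation.
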