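# Methods

## Model

The simulation is an individual-based, discrete-time model of a closed
population on a bounded `N × N` lattice. `n = a·N²` individuals (exactly
half male) are placed independently and uniformly at random; there is no
birth, death, removal, or exclusion (any number of individuals may share
a cell). Each time step, individual `i` relocates with probability `m`
if male and `1 − m` if female — the single-parameter encoding of
movement asymmetry — and, conditional on moving, draws its destination
`j` with probability proportional to `1/d_ij`, the Euclidean distance
between cell centres on the integer lattice.

Assumptions worth making explicit:

- **Self-transitions are excluded from the kernel.** `1/d_ii` is
  undefined; "moving" means relocating to a different cell, and staying
  put happens only through the Bernoulli movement draw. The kernel row of
  each source cell is therefore a categorical distribution over the other
  `N² − 1` cells.
- **Edges are physical boundaries.** No wrap-around and no reflection
  rule: border cells simply have fewer nearby destinations, which is the
  entire boundary treatment. A consequence is that the kernel's
  stationary distribution is centre-heavy (the chain is a reversible
  random walk on a weighted graph, so stationary mass in a cell is
  proportional to that cell's total `1/d` weight).
- **Both sexes share one kernel and hence one stationary distribution.**
  Movement probability only sets the pace, not the destination law. The
  kernel is long-ranged (mass decays like `1/d`), so even the sedentary
  sex equilibrates within a handful of moves; the 100-step burn-in is
  ample at every movement probability in the studied range.
- Coordinates are reported 1-based `(row, column)`; internal arithmetic
  is flat 0-based row-major.

## Sampling methods

Both observers watch the *same* population trajectory within a replicate;
neither removes animals.

**Passive capture.** `max(1, round(effort · N))` transects (rounding
half away from zero, so 10% effort on an 8-row grid still installs one
transect) are placed once per replicate on rows drawn uniformly *without
replacement* — duplicates would silently reduce realized effort. Each
transect spans `floor(N/2)` contiguous cells starting at a column drawn
uniformly from `1..floor(N/2)`, with stations on alternating cells
beginning with the first (hence `ceil(length/2)` stations). Capture is
triggered by **arrival only**: an individual whose movement step ends on
a station is recorded; one sitting still on a station is not
re-evaluated. Detectability plays no role in this method by construction.

**Active search.** One transect per day with the same geometry (row
uniform over all `N` rows, start column uniform over `1..floor(N/2)`),
re-drawn independently each day, with **every** cell searched. Each
individual present in a searched cell is recorded with its sex's
detectability. Active transects may overlap trap transects; the methods
are independent observers and do not interfere.

The daily order is fixed: movement → trap check (using that step's moved
mask) → active search on post-movement positions.

Start columns never exceed `floor(N/2)`, so transects concentrate
coverage on the left-central columns and never reach column `N` on even
grids; both methods share this geometry, so it cancels out of the
between-method comparison.

## Test and classification

Unique-capture counts per sex (set semantics over individual identities)
are tested against the true 1:1 split with the Pearson chi-square
goodness-of-fit statistic on df 1, no continuity correction — the
conventional default for a two-category GOF test. A replicate is
`male_biased` or `female_biased` when `p < α` (direction from the count
comparison; the test itself is two-sided), `unbiased` when `p ≥ α`, and
`no_data` when a method captured nothing. `no_data` is tallied in its own
column and deliberately *not* counted as unbiased, which would flatter a
method that simply failed to sample.

A calibration subtlety: the chi-square compares the male count against
`Binomial(T, 1/2)`, but once a large fraction of the population is
marked, the conditional split of captures is hypergeometric — a
finite-population correction the test ignores — so the realized test
size falls well below the nominal `α` as surveys lengthen or effort
grows. Under symmetric parameters both methods are therefore classified
unbiased in essentially every replicate, and the rejection rate can only
drift *below* nominal along effort/days sweeps. This conservatism is a
property of applying the standard test to saturating mark-recapture
counts, not an implementation artifact.

A related consequence: movement asymmetry leaves active search
essentially unbiased here. Both sexes sample the same stationary spatial
law, so with equal detectability the unique-capture probabilities match;
the only channel for a movement effect on active search is incomplete
mixing of the sedentary sex, and the burn-in removes it. The trap method,
which records arrivals and therefore multiplies every capture chance by
the movement rate, carries the full force of the asymmetry — hence the
passive method degrades dramatically while active search stays flat.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `grid_resolution` (N) | grid side, cells | 20 | mid-range of the studied 10–55 span; 1600 individuals |
| `density_multiplier` (a) | individuals per cell on average | 4 | standard density used throughout |
| `male_move_prob` (m) | male per-step move probability | 0.5 | symmetric null |
| detectabilities | per-encounter detection per sex | 0.5 / 0.5 | symmetric null, mid-scale |
| `passive_effort` | transects as fraction of N | 0.10 | one trap line per 10 rows, the canonical low-effort design |
| `burn_in_steps` | pre-survey movement steps | 100 | equilibrates the slowest sex with a wide margin |
| `sampling_days` | survey length | 100 | standard full-length survey |
| `replicates` | runs per combination | 100 | full-simulation batch size |
| `alpha` | chi-square test size | 0.05 | conventional |

Standard sweep grids: N ∈ {10…55 step 5}, days ∈ {35…350 step 35},
m ∈ {0.5…0.95 step 0.05}, effort ∈ {0.10…0.55 step 0.05}, equal
detectability ∈ {0.1…1.0 step 0.1}, opposed detectabilities
(DeMa, DeFe) ∈ {(0.1,0.9)…(0.9,0.1)} with sum fixed at 1 (the endpoint
of this last grid is a choice; the sweep is symmetric about (0.5,0.5)).
Interaction sweeps rerun the days and effort grids under movement
scenarios m ∈ {0.6, 0.7, 0.8, 0.9} or detectability scenarios
{(0.1,0.9)…(0.4,0.6)}.

## Reproducibility and numerics

- Replicate `i` of a combination owns the RNG stream
  `default_rng(seed + i)`; combinations within a sweep space their base
  seeds by `max(1000, replicates)`. Distinct integer seeds yield
  independent PCG64 streams, results are independent of execution order,
  and any single replicate can be re-run in isolation.
- The kernel is built once per `N` (cached) and shared across replicates;
  rows sum to 1 within 1e−12. Destination draws use an exact inverse-CDF:
  per-row cumulative distributions are offset by their row index into one
  globally sorted array, so a single vectorized `searchsorted` performs
  all per-row categorical draws with no approximation.
- Degenerate inputs: a 1 × 1 grid cannot support movement or transect
  placement and is rejected at kernel/layout construction; `a·N²` odd is
  rejected at configuration time; a zero-capture method is classified
  `no_data`, never an error.
- Ties in the chi-square cannot produce a directional label: equal counts
  give statistic 0 and p = 1.

## What the simulation does and does not emulate

The generator produces the study conditions themselves — there is no
external data. It emulates sex-asymmetric movement on a homogeneous,
edge-limited habitat and two idealized observers with perfect traps and
constant per-encounter detectability. It does **not** emulate microhabitat
preferences, sex-specific trappability (trap-shyness/-happiness),
observer skill variation, demographic turnover, home ranges, or
correlated movement — so a passing suite shows the *estimator logic* is
right under these dynamics, not that any particular field system behaves
this way. Applicability to real surveys also presumes marked (or removed)
individuals, since unique-capture counting is built into the statistics.

## Problem sizes

The test suite and the acceptance script run sweeps at a 20 × 20 grid
with 50 replicates per combination (the grid-size sweep itself spans
10–30), which this package treats as its standard reduced scale: effect
directions and saturation points are unchanged from larger runs while a
full sweep completes in tens of seconds. The full-scale grids remain
available through `SweepSpec`/CLI flags.
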