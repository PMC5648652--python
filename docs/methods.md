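# Methods

## Model

`partmig` is an individual-based, spatially explicit metapopulation model of
a haploid species with discrete, non-overlapping generations on a grid of
`x_max × y_max` breeding patches (default 100 × 25), each with carrying
capacity `K`. Two opposing linear gradients run along x, emulating a
pole-to-equator trajectory of the breeding range: nominal resident winter
survival 0.01·x (0.01 at x = 1 up to 1 at x = 100) and a reproduction
location factor falling from 1 to `1 − (1 − c_loc_r)` (0.8 at the default).
Every individual carries one continuous heritable trait, the migration
threshold T ∈ [0, 1], expressed as a binary phenotype by comparison against
the locally expected resident winter survival — the threshold model of
quantitative genetics applied to migratory behavior.

A generation applies, in order: migration decision, winter survival,
dispersal, reproduction with inheritance and mutation, parental death.

### The decision fixed point

The decision compares T against the winter survival a would-be resident
anticipates, *including* the density of residents that the decisions
themselves produce. We resolve this circularity with a deterministic fixed
point per patch: sort thresholds ascending; since the n-th smallest
threshold increases in n while survival `s_r(x, n)` decreases, the condition
"n-th smallest threshold ≤ s_r(x, n)" holds on a prefix, and the realized
resident count n\* is the largest such n. The n\* smallest-threshold
individuals stay; ties at the marginal threshold value are broken uniformly
at random; equality of expected survival and T means staying (migrate iff
s < T strictly, so T = 0 is an obligate resident). This is the unique
self-consistent partition under perfect local knowledge. Two weaker
alternatives (sequential random-order decisions; previous-generation
density) were considered and rejected: both let individuals act on stale or
order-dependent information, contradicting the perfect-prediction
assumption. Note a consequence of self-inclusive density: a *single*
T = 0.5 individual in an otherwise empty column is marginally affected by
its own density (factor 1 − (1 − c_dens_s)/K), so statements like "T = 0.5
switches phenotype at x = 50" refer to the decision rule evaluated at zero
density, `s_r(x, 0) = 0.01x`.

### Other stage conventions

- **Winter.** Migrants survive with constant `s_m` (they winter outside the
  modelled landscape); residents with `s_r(x, n*)`, the density fixed at
  decision time. All survival draws are independent Bernoulli.
- **Dispersal.** With probability `d` a survivor moves to a destination
  uniform over the cells within Chebyshev distance `delta`, excluding the
  origin. The Chebyshev metric is a choice — the distance kernel is not
  otherwise determined — made for isotropy on a square grid. Borders
  reflect ("bounce"): out-of-range coordinates fold back as x′ = 2 − x at
  the low edge and x′ = 2·x_max − x at the high edge (implemented as a
  triangular-wave fold, robust to multiple bounces); draws whose reflected
  destination is the origin cell are re-drawn.
- **Reproduction.** Brood size No ~ U{0,…,max_brood}; the corrected
  offspring number R = No·c_tot (× `migr_repro_factor` for migrant parents)
  is generally non-integer and is realized by stochastic rounding,
  floor(R) + Bernoulli(frac(R)), which preserves E[R] exactly without a
  systematic floor/ceiling bias. Offspring inherit the mother's T; with
  probability `m` the value is replaced by a uniform draw on [0, 1] (the
  53-bit float grid; the open/closed distinction is immaterial at double
  precision). Parents die after reproduction.

### Parameters

| name | default | meaning |
|---|---|---|
| `K` | 100 | carrying capacity per patch (density scale of both density terms) |
| `s_m` | 0.5 | migrant winter survival |
| `c_dens_s` | 0.6 | survival density dependence (1 = none; s_r hits 0 at density 2.5 K) |
| `c_dens_r` | 0.4 | reproduction density dependence |
| `c_loc_r` | 0.8 | reproduction location dependence (factor 0.8 at x = 100) |
| `m` | 1e-4 | per-offspring mutation probability |
| `d` | 0.1 | per-survivor dispersal probability |
| `delta` | 2 | maximum dispersal distance (cells) |
| `x_max`, `y_max` | 100, 25 | landscape extent |
| `max_brood` | 6 | brood-draw maximum |
| `surv_delta` | 0 | additive shift of the survival gradient (±0.2 in change scenarios) |
| `migr_repro_factor` | 1 | migrant reproduction multiplier (0.8 in the change scenario) |

## Scenarios

Initialization fills every patch of the chosen region at carrying capacity
K: the whole landscape ("compl"), the polar edge columns 1–10 ("migr"), or
the equatorial edge columns x_max−10…x_max ("res"). Initial diversity is
maximum (T ~ U(0,1] per individual), zero (T = 0.5, the value that is
beneficial across most of the landscape), or zero-but-fitted (T = 0.1 for
resident-side, T = 0.9 for migrant-side initializations — already adapted to
the starting edge). Abrupt changes — resident survival ± 0.2 (additive on
the nominal gradient, clamped to [0, 1]) or migrant reproduction × 0.8
(multiplicative; "20% decreased reproductive success") — switch on as a step
function at `change_generation` (default 300, after demographic
equilibrium) and stay on. The default catalog crosses these options into 24
experiments: the 6 edge-initialization expansions without change, all 8
valid region × diversity pairs under each survival shift (16), and the
reproduction change on the two whole-landscape initializations (2). The
whole-landscape zero-diversity scenario receives survival changes at
generation 0, so no mutational diversity accumulates before the change; the
catalog is fully overridable from the run configuration. Run length is
configurable (default 1000 generations); "years" equal generations in this
discrete-generation model.

Each replicate uses `numpy.random.default_rng(base_seed + replicate_index)`
and a fixed stage-level draw order, making every trajectory bit-reproducible
from `(scenario, params, seed)`.

## Analysis

Phenotypes are recorded immediately after the decision stage, summed per
x-column over the `y_max` patches; thresholds are averaged per column.
The 1% border criterion is applied per column — residents as a fraction of
that column's individuals — which is the reading under which "the smallest
x-location where …" is well defined; a landscape-wide denominator would
compare a column count against a landscape total. Borders are undefined
(NaN) when no column qualifies; the zone midpoint may be half-integer.
Newborns that never faced a decision (simulation end) are excluded from
phenotype counts. The range front is the most advanced column occupied by at
least one individual (the occupancy cutoff is configurable); replicate
aggregation reports the across-replicate mean, sample SD (ddof = 1, zero for
a singleton) and contributing count per generation, excluding undefined
values.

## Problem sizes and what the tests show

The acceptance-style simulations run a reduced landscape — 100 columns × 5
patches, K = 50, 10 replicates — chosen so the full scenario battery stays
desk-scale. The structure of the model is density-*ratio* driven (both
density terms depend on N/K), so halving K and shrinking y leaves the
equilibrium zone geometry essentially unchanged; what does change is the
mutation supply (births × m), roughly 10× smaller than at full scale.
Mutation-limited processes therefore get proportionally longer horizons:
expansion runs are given 400 (zero diversity), 800 (maximum diversity) or
1000 (fitted T) generations, and colonization times are censored at the
horizon. Equilibrium structure is assessed on per-column phenotype profiles
time-averaged over a ~40–50-generation window, because the instantaneous 1%
borders jitter: one resident appearing for one generation in a small column
moves the border across half the landscape. The change scenarios are checked
for tripartite structure at their pre-change equilibrium; the first ~100
post-change generations are a transient (the survival-decrease response in
particular keeps moving well past that window, with 1–3% migrants pinned at
the equatorial edge while the zone presses against the end of the
landscape), and the post-change states are instead checked for the direction
of the zone shift and for the absence of extinction.

The synthetic landscape *is* the study system here — there is no external
data — but the usual caveats of the model apply to any transfer to real
species: haploid asexual inheritance of a single locus, perfect survival
prediction, deterministic gradients without environmental stochasticity, and
reflecting borders. Passing tests demonstrate the internal logic
(self-consistent decisions, density regulation, zone formation and its
response to forcing), not a calibration to any empirical population.

## Known limitations

- The decision fixed point can leave a marginal individual indifferent in
  knife-edge configurations (its threshold lies between the survival at n\*
  and at n\*+1 residents); the largest self-consistent resident set is used,
  which is the stable choice (joining would make its stay unviable).
- `aggregate_replicates` requires a shared generation grid; runs recorded at
  different cadences must be re-recorded, not resampled.
- Single-cell landscapes (x_max = y_max = 1) silently skip dispersal, as
  there is no destination cell.
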