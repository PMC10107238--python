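# Methods

`groupskew` implements an optimisation theory of group size and reproductive
skew for cooperatively breeding, single-sex (female) groups.  Two models are
provided: a concrete *group economy* with integer group compositions and
population-density feedback, and a general *life-history* model in
continuous variables whose constrained maxima and gradient-flow trajectories
describe how a lineage could evolve from solitary to social living.  Both
rest on the same two ingredients: increasing-then-diminishing returns to the
number of cooperating producers, and economies of scale in reproduction that
reward concentrating births in few females.

## The group economy

A representative group has `n` producers and `R` reproductive females inside
a conspecific population of density `D`.  Annual energy output is

    Y(n, D) = D^(-gamma) * (a2 n^2 - a3 n^3),

a cubic with increasing returns at small `n` and eventual collapse, scaled
down by density through `D^-gamma` (crowding shrinks each group's foraging
base).  Each member eats `s`, so the group surplus is `S = Y - s (n + R)`.
The surplus is split equally among reproductives; each reproductive's share
net of her own maintenance ration must cover a quadratic total birth cost:

    S/R - s = c0 + c1 B + c2 B^2.

Births per reproductive are the positive root `B(S, R)`; no real positive
root means zero births.  The fixed cost `c0` (reproductive organs, mating,
nest) is spread over more births as fertility rises while `c2 B^2`
eventually dominates, so average cost per birth is U-shaped with an
efficient brood size `sqrt((c0 + s)/c2)`.  Note the accounting convention: a
reproductive's subsistence is deducted both inside `S` and again from her
reproductive ration.  We keep this convention deliberately — it is the one
under which the model's characteristic viability bounds (16 and 53 producers at
`D = 1`) are reproduced exactly — and read the extra `s` as the incremental
metabolic cost of being in reproductive condition.

Defaults: `a2 = 2`, `a3 = 0.03`, `gamma = 0.7`, `s = 20`, `c0 = 20`,
`c1 = 3`, `c2 = 0.1`, adult death rate `0.4`/y (the `baseline-economy` preset).

`optimize_group` is an exhaustive integer search over `n ∈ [1, 200]`,
`R ∈ [1, 10]` (production collapses well before `n = 200` at the defaults),
under one of two objectives — total surviving births, or the per-capita
birth rate — with ties broken toward smaller `n`, then smaller `R`.  The
per-capita denominator is configurable: members only (`n + R`, the default)
or members plus the newborn offspring.  Because the birth-cost curve is
convex, the optimizer will happily use two or three reproductives where a
single female would be pushed past her efficient brood size; at unit density
the per-capita optimum is `(n, R) = (33, 2)` and the total-births optimum
`(39, 3)` (a near-tie with `(39, 2)`).

Subtracting the death rate from the best attainable per-capita rate gives
the population growth rate at each density; `equilibrium_density` brackets
its root by bisection (tolerance 1e-6 in `D`, default bracket `[0.5, 5]`).
Densities at which no configuration is viable are treated as zero births
inside the bisection, i.e. growth `-death_rate`, so the growth curve is
defined on the whole bracket; the user-facing `growth_rate` instead raises,
to make infeasibility explicit.  Because per-capita-optimal groups weakly
dominate total-births groups in rate at every density, their equilibrium
density is strictly higher, and total-births groups placed at that density
decline — the demographic argument for why selection favours rate
maximisers.

## The life-history model

A group holds `N` females, a fraction `p` of them reproductive.  Becoming
reproductive costs a fixed fraction `t` of lifetime; reproducing costs a
further variable fraction `x ≤ 1 - t`.  Producer-equivalents are
`n = N (1 - p t - p x)`.  Production is a shifted logistic

    g(n) = A [ 1/(1 + q^(n0 - n)) - 1/(1 + q^n0) ],

with `g(0) = 0`, inflection near `n0`, steepness `q` and scale `A`.  After
subsistence `N s`, the surplus funds reproduction:
`m = (g(n) - N s)/(N p)` per reproductive.  Births per reproductive follow a
Cobb-Douglas technology, homogeneous of degree one,

    b = f(m, x) = alpha m^beta x^(1-beta),

with `beta` the *food intensity* of reproduction (`beta` near 1: births
limited by provisioning, e.g. large litters; `beta` small: limited by
maternal time, e.g. singleton births).  Fitness is the per-member birth rate
`pi = p f(m, x)`, maximised subject to `N ≥ 1`, `1/N ≤ p ≤ 1`,
`0 < x ≤ 1 - t`.

Analytic derivatives (cross-checked against central differences in the test
suite):

    dpi/dN = f_m (n g'(n) - g(n)) / N^2
    dpi/dp = f - f_m [ (x + t) g'(n) + m ]
    dpi/dx = p (f_x - f_m g'(n))

Group size matters only through whether producers sit below or beyond the
point where the marginal product equals the average product; `optimal_n`
solves `n g'(n) = g(n)` (scale-invariant in `A`) by bracketing and Brent's
method, and is verified against a 10^4-point grid argmax of `g(n)/n`.

Two structural results organise every optimum.  First, with Cobb-Douglas
reproduction and `t > 0`, `x` and `p` cannot both be interior-stationary:
substituting the `x`-stationarity condition `f_x = f_m g'` into `dpi/dp`
gives `dpi/dp = -f (1 - beta) t / x < 0`, and symmetrically the
`p`-stationarity condition forces `dpi/dx = p f (1-beta) (1/x - 1/(x+t)) > 0`.
`mutual_exclusion_check` validates this numerically on seeded random
parameter draws (the sampler keeps `t ≥ 0.01` because at `t = 0` the
`p`-derivative degenerates and any `p` is optimal).  Second, the optimum is
therefore always on a boundary, and falls into three regimes as `beta`
varies with everything else fixed:

* **single reproductive** (`p = 1/N` active, `x` interior): food-intensive
  reproduction; helpers provision one part-time-producing breeder;
* **stage-restricted** (`x = 1 - t` active, `p` interior): time-intensive
  reproduction; every female breeds, but only during one life stage, at the
  maximum possible time allocation;
* **double corner** (both active): one fully specialised reproductive.

At the single-reproductive corner the interior-stationary reproductive time
is `x* = ((1-beta)/beta) n* (1 - N s / g(n*))`, which is bounded above by
`((1-beta)/beta) n*`.  With the calibrated `n* = 21.47` and `t = 0.2` this
means `x` can only reach its ceiling `0.8` for `beta ≲ n*/(n* + (1-t)) ≈
0.964`: the double-corner regime occupies a narrow band (numerically about
`beta ∈ [0.955, 0.96]`) between the stage-restricted regime below and the
single-reproductive regime above.  Consequently the shipped `intermediate`
preset (`beta = 0.99`) converges to the single-reproductive corner, not the
double corner, for *any* production scale; the package reports what the
model implies rather than forcing a classification.

`maximize_fitness` runs SLSQP on `-pi` with the coupled bound `N p ≥ 1` and
the energy constraint `g(n) ≥ N s` as inequalities and analytic gradients;
in the infeasible region the objective becomes a penalty on the energy
deficit so iterates cannot stall there.  A point whose projected-gradient
norm is below `1e-6 (1 + |pi|)` counts as converged even when the SLSQP line
search ends at numerical resolution.  Bounds are classified active when the
state is within `1e-6` of them with a non-improving inward derivative.

## Calibration and presets

The production curve is under-determined: only the target optimum
`n* = 21.47` pins it down.  `calibrate_g` solves `n0` from
`optimal_n(q, n0) = n*` at fixed steepness (`q = 1.3` by default; `A`
cancels), then scales `A` so a reference group of `n* + 1` members produces
`margin` times its subsistence at the optimum.  The default `margin = 25`
is chosen so the solitary ancestral state (`N = 1`, `p = 1`, `x = 0.3`,
hence `n = 0.5` producer-equivalents) clears subsistence — evolutionary
trajectories must be able to start there — and the reported optimum classes
are stable across margins with that property.  The three life-history
presets share one calibrated curve with `t = 0.2`, `s = 100`, `alpha = 1`
and differ only in `beta`: food-intensive `0.995`, time-intensive `0.25`,
intermediate `0.99`.  With these values the food-intensive optimum has a
single reproductive comprising `p ≈ 0.046 ≈ 1/(n*+1)` of the group, and the
time-intensive optimum has `p ≈ 0.72` of females in the reproductive stage
at `x = 0.8` — both with `n ≈ n*`.

`random_params` draws valid parameter sets and feasible states (seeded,
reproducible): `t ∈ [0.01, 0.5]`, `s ∈ [10, 200]`, `beta ∈ [0.05, 0.95]`,
`q ∈ [1.05, 2]`, `n0 ∈ [5, 40]`, with `A` solved per-draw so the sampled
state carries a surplus of 1.2-4x subsistence.  These draws fuel the
gradient cross-checks and the mutual-exclusion validation; they emulate a
wide range of energetic regimes but, like everything here, they are
single-sex, unstructured by age, and deterministic — passing tests say
nothing about stochastic demography or explicit kin structure.

## Evolutionary trajectories

`ascend` integrates projected gradient flow of `pi` over `(N, p, x)`.
Steepness is measured in a relative-group-size metric,
`ds^2 = (dN/N)^2 + dp^2 + dx^2` (equivalently: steepest ascent in
`(ln N, p, x)`).  Selection plausibly acts on proportional changes in group
size, and the metric also cures a numerical pathology: fitness is extremely
flat in absolute `N` along boundary valleys (condition numbers near 4e5 at
the stage-restricted optimum), which stalls a plain Euclidean flow; the
rescaling drops the condition number to about 70 while leaving every
stationary point, and hence every endpoint, unchanged.  Steps backtrack on
any fitness decrease and expand while fitness keeps improving, so recorded
fitness is non-decreasing by construction; bounds are handled by projection
plus removal of the outward gradient component (the coupled bound
`p ≥ 1/N` has normal `(1/N, 1, 0)` in the log metric).  Integration stops
when the projected-gradient norm falls below `tol (1 + |pi|)`
(`tol = 1e-8`), when no ascent step above machine size exists, or at
`max_steps = 1e5`.  Pseudo-time has no biological unit.

Two-dimensional flows over the `(p, x)` plane keep the plain Euclidean
metric there — that is what makes them cross isofitness contours at right
angles — and obtain `N` from an *n-policy*: `FIXED_OPTIMAL_N` solves
`N = n*/(1 - p (t + x))` and flags points where that `N` violates
`p ≥ 1/N`; `SOLVE_N_FROM_STATE` clips the same `N` into the feasible
interval (fitness is unimodal in `N` with its peak where `n = n*`, so the
clipped value is the constrained optimum; the two policies agree wherever
the solved `N` is feasible).  On the plane, the coupled bound becomes the
curve `p (n* + t + x) = 1`; the flow projects onto it and slides along its
tangent `(-p^2, 1)`.  The plane integrator adds two curvature guards —
never step past the one-dimensional line maximum, and reject steps across
which the gradient rotates by more than `acos(0.9998) ≈ 1.1°` — so the
discrete path tracks the continuous flow through stiff valleys (with
`beta = 0.995`, `pi ∝ x^0.005` makes the landscape's `x`-curvature of order
1e6 near small `x`; a naive line-maximising scheme zigzags across such
valleys and its chords run *along* the isoquants instead of across them).
With these guards the worst interior |cosine| between path segments and
contour tangents is about 0.010 for all three presets.

`orthogonality_check` measures that cosine against a matching isoquant
field, excluding segments that touch an active bound (projection breaks
orthogonality there by design) and segments in the vanishing-gradient
neighbourhood of the optimum, where no contour is being crossed.

`beta_sweep` classifies the optimum on a grid of food intensities using the
bounded optimizer; on the shipped production curve the regimes are
stage-restricted for `beta ≤ 0.95`, double-corner in roughly
`[0.955, 0.96]`, and single-reproductive from `0.965` up, in one contiguous
band each.

## Numerical choices and limitations

* Producers and reproductives are integer counts in the economy; densities,
  rates and energies are continuous.  The life-history model is fully
  continuous.
* Quadratic birth roots: only the "+" branch; complex or non-positive roots
  mean zero births, never an exception.  Infeasible states (`m ≤ 0`) are
  flagged (NaN fitness), not raised, except where an operation requires
  feasibility (gradients, flow starts).
* `x`'s open lower bound is floored at 1e-12; fitness tends to 0 there, so
  no optimum is lost.
* Ties, brackets and tolerances: integer ties toward smaller `n` then `R`;
  bisection 1e-6 in `D`; Brent 1e-10 in `n`; gradient cross-checks at
  `h = 1e-6` relative, agreement required to 1e-5 of the gradient norm.
* The test suite and the acceptance script run the full model at its
  shipped sizes (search bounds 200x10, 10^4-point oracle grids, 1000-draw
  theorem validation, 20-start convergence runs); everything completes in
  about a minute on one core.
* Known limitations: no males, no age or generation structure, no
  stochastic demography, no explicit fissioning or dispersal, no
  relatedness accounting.  The models describe where selection gradients
  point, not how fast real lineages move or whether kin structure lets them
  get there.
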