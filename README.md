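# groupskew

Optimal group size and reproductive skew under increasing returns to
cooperation — a simulator for theoretical evolutionary ecologists studying
cooperative breeding, Allee effects and the evolution of sociality.

Many social animals (wild dogs, mole rats, social insects, helper birds)
both *produce* cooperatively and *restrict reproduction* to one or a few
females.  `groupskew` implements an optimisation theory in which both
follow from the same economics: group output rises faster than linearly
with the number of producers before diminishing returns set in, and the
average cost of a birth falls as a female's fertility rises (fixed costs of
being reproductive are spread over more offspring).  Groups that
concentrate births in few, well-provisioned females can therefore convert
the same surplus into more surviving offspring per member.

The package has two layers:

* **Group economy** (`groupskew.economy`) — integer producers `n` and
  reproductives `R` at conspecific density `D`, with

      Y = D^(-γ) (a₂n² − a₃n³),    S = Y − s(n+R),
      S/R − s = c₀ + c₁B + c₂B²   (births B per reproductive),

  exhaustive search for the optimal composition under either a total-births
  or a per-capita-rate objective, viability bounds, and the population
  equilibrium density where the optimal birth rate equals the death rate.

* **Life history** (`groupskew.lifehistory`, `.trajectory`) — continuous
  group size `N`, reproductive fraction `p` and reproductive time `x`, with
  producer-equivalents `n = N(1 − pt − px)`, logistic production `g(n)`,
  Cobb-Douglas reproduction `b = α m^β x^(1−β)` and per-member fitness
  `π = p·b` maximised subject to `N ≥ 1`, `1/N ≤ p ≤ 1`, `0 < x ≤ 1−t`.
  Analytic gradients, the average-equals-marginal condition
  `g'(n*) = g(n*)/n*`, a theorem that `x` and `p` are never both interior
  at an optimum, a bounded optimizer, and projected-gradient-flow
  evolutionary trajectories with isofitness fields over the `(p, x)` plane.

`groupskew.scenarios` ships the calibrated presets (a `baseline-economy` economy and
three life-history presets that differ only in the food intensity β of
reproduction), and `groupskew.cli` exposes everything as the `groupskew`
command.

## Worked example

Optimal group composition at unit density, under both objectives:

```text
$ groupskew economy scan --density 1.0
D=1 objective=per-capita: n=33 R=2 Y=1099.8900 S=399.8900 B_total=55.4272 rate_pc=1.583633

$ groupskew economy scan --density 1.0 --objective total
D=1 objective=total: n=39 R=3 Y=1262.4300 S=422.4300 B_total=60.3466 rate_pc=1.436823
```

The rate-maximising group (35 members, two breeders) is smaller than the
birth-maximising one (42 members, three breeders) and achieves a higher
per-capita rate — 1.58 vs 1.44 surviving births per member-year.  Groups
with fewer than 16 or more than 53 producers cannot sustain a single
reproductive at all (`viable_producer_range`).  As the population grows,
density discounts output by `D^-0.7` until the best attainable rate meets
the 0.4/y death rate:

```text
$ groupskew economy equilibrium --objective per-capita
equilibrium density (per-capita): 1.639113
$ groupskew economy equilibrium --objective total
equilibrium density (total): 1.631797
```

Rate maximisers equilibrate at strictly higher density; at that density the
birth-maximising groups have negative growth and go extinct — which is why
selection favours per-capita rate.

On the life-history side, the optimum regime flips with the food intensity
β of reproduction:

```text
$ groupskew lh optimize --preset food-intensive
class=single-reproductive converged=True N=21.828892 p=0.045811 x=0.104934 n=21.523958 m=54132.637366 pi=2322.013726

$ groupskew lh optimize --preset time-intensive
class=stage-restricted converged=True N=77.045931 p=0.721335 x=0.800000 n=21.470000 m=872.147425 pi=3.315904
```

When food dominates reproduction (β = 0.995) the optimum is a single
breeder — `p = 1/N ≈ 0.046`, one female provisioned by ~21 helpers, herself
producing part-time.  When maternal time dominates (β = 0.25) every female
breeds but only during a life stage: reproductive time sits at its ceiling
`x = 1 − t = 0.8` and 72% of females are in the reproductive stage at any
moment.  Both optima field `n ≈ 21.47` producer-equivalents, the point
where the marginal product of a producer equals the average product.

`groupskew traj run --preset food-intensive --out traj.csv` integrates the
fitness-gradient flow from a solitary ancestor (`N=1, p=1, x=0.3`) to that
optimum, and `groupskew figures economy` / `groupskew figures landscape` draw the
four-panel economy and isoquant/trajectory figures.

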