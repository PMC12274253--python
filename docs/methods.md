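# Methods

## Model structure

The simulator advances a nine-dimensional state — six protocell class
densities (three species × young/old) and three nutrient pools (x, x1, x2) —
over the *modeling time points*, the sorted union of the three species'
operation clocks t<sub>s0</sub> + k·τ<sub>s</sub>. Each time point has two
sub-steps:

1. **Pre-competition update.** Pools receive the previous point's free and
   hidden amounts, the environmental drift r<sub>n</sub>·Δt (r = b, b1, b2),
   and one unit of each produced nutrient per survivor of every species
   operating *now* (production is credited at the end of the producer's
   cycle, i.e. at its next operation time, not at the next grid point).
   Negative totals are clamped to zero. An operating species' young density
   becomes the survivor total of its previous operation time and its old
   density the surviving-young count; non-operating species carry over
   unchanged.
2. **Competition.** For each nutrient, total demand D<sub>n</sub> sums the
   densities of the operating classes that must absorb it (young protocells
   already hold their parent's products and demand only the rest; old
   protocells demand all three). Each class survives with density
   Q̃·∏ min(Q<sub>n</sub>/D<sub>n</sub>, 1) over its demand set — the
   expected outcome of uniform random sharing. Unabsorbed surplus is *free*;
   the part absorbed by protocells that nevertheless died is *hidden* and
   re-enters the pools at the next time point.

### The product-of-fractions operator

The only-generalist time point is also described by an equivalent sequential
procedure (young share x first, the remainder passes to the old, who then
compete for x1, then x2, always with the *pre-competition* old density in the
denominator). That denominator choice is what makes the sequential procedure
collapse to the product form: per-nutrient sharing is proportional among all
demanders regardless of success on other nutrients. The package adopts the
product form as the single competition operator for every active-species
combination, because it is the unique extension of the one-species case under
those sharing assumptions. The equivalence on the one-species case is held as
a permanent regression property (`tests/oracles.py` keeps a deliberately
literal transcription of the sequential min/max formulas; the suite compares
the two routes on 10,000 randomized inputs at 1e−12 relative tolerance), and
per-nutrient conservation Q = free + consumed + hidden is asserted along all
headline runs.

At coincident operation times of several species, each nutrient is shared
jointly and proportionally across all demanding classes of all operating
species; the successful reproduction of the commensurable-clock equilibrium
(below) supports this reading.

### Parental nutrients of failed young

The free/hidden bookkeeping returns environmentally absorbed units of failed
protocells but not the parent-supplied units that failed *young* protocells
carry; these vanish from the budget. The default follows that convention.
For users who want strict mass conservation, `return_parental_nutrients`
(config `options` block, default off) credits the parent-supplied units of
failed young to the hidden pools as well. All shipped presets use the
default; none of the headline results change qualitatively under the flag.

## Scheduling and numerics

* Operation times are generated directly as t<sub>s0</sub> + k·τ<sub>s</sub>
  (never by cumulative summation), so no floating drift accumulates over the
  horizon of 200 time units (≈ 130–400 grid points for the shipped presets).
* Two candidate times are merged into one grid point iff
  |Δt| ≤ 1e−9·max(1, t). With doubles this cannot falsely merge
  incommensurable clocks over the studied horizons (adjacent distinct ticks
  of the preset clocks stay ≥ 1e−2 apart) and cannot split commensurable
  ones (identical arithmetic gives bit-identical values).
* Reproduction times involving π are entered as expression strings
  (`"pi/2"`, `"pi/2 * pi/4 + 0.2"`) evaluated to full double precision at
  config load; a truncated decimal would make the clocks commensurable and
  change the grid structure.
* The grid's closed endpoint includes t = horizon.
* Densities are real-valued throughout; no rounding anywhere. Negative pool
  intermediates are clamped to zero at the pre-competition step only.
* Case labels I–VII name the seven nonempty active-species subsets
  ({T0}→I, {T1}→II, {T2}→III, {T0,T1}→IV, {T0,T2}→V, {T1,T2}→VI,
  all→VII). All behaviour is keyed on the active set itself, so the labels
  are pure bookkeeping in trajectory output.

## Survival classification

A species is *extinct* iff its total post-competition density at its final
operation time is ≤ ε, with ε = 1e−9 density units by default. Survivor
fractions are multiplicative, so exact zeros arise only through an empty
pool; the threshold also catches asymptotic decay without misclassifying any
of the preset outcomes. The extinction time is the first operation time from
which the density stays ≤ ε.

## Averaging convention

Reported means are arithmetic averages over every modeling time point of the
full horizon, using post-competition protocell densities and pre-competition
nutrient pools (`mean_mode="post_pre"`). This convention reproduces the
published time averages of the x-inflow sweep to the printed integer
(mean QT 16184/32305/48474 and mean Qx 7881/20568/31591 for
b = 10000/20000/30000), which the acceptance script recomputes. The three
alternative conventions (pre-competition protocells and/or post-competition
pools = free + hidden) are available through `mean_mode`; they differ by up
to ~20% (pre-competition protocell counts include the about-to-die) and do
not match the published values, which is how the default was identified.

## Equilibrium analysis

With both specialists extinct and τ1 = τ2 = τ0/2, the x1/x2 pools grow
without bound, so the generalist is assumed fully supplied with x1 and x2.
Composing the two time points of one generalist cycle then yields the
contracted map on (X, u, v) = (pre-competition x pool, young, old):

    f  = min(X/(u+v), 1)        (f = 1 when u+v = 0)
    X' = max(X − (u+v), 0) + b·τ0
    u' = f·(u+v),  v' = f·u

Its scarce-regime fixed point is (b·τ0, b·τ0, φ·b·τ0) with φ = (√5−1)/2;
the post-competition survivors are QT01\* = φ·b·τ0 and QT02\* = (1−φ)·b·τ0.
The map's equivalence with two steps of the full simulator (saturated x1/x2)
is tested at 1e−12.

* **Fixed point**: direct iteration, convergence when the step falls below
  1e−12·b·τ0 (the map is a local contraction; ~60 iterations suffice).
* **Stability**: the Jacobian is differentiated by central differences with
  step 1e−6·b·τ0. The fixed point lies strictly inside the clamped branch
  (u\*+v\* = (1+φ)·b·τ0 > b·τ0 = X\*), so the stencil crosses no kink. The
  spectrum is {0, 0, −φ²}; all moduli < 1, hence local asymptotic stability,
  and by degree-1 homogeneity of the scarce branch the spectrum is
  independent of b (asserted numerically).
* **Self-consistency of the abundance assumption**: at the fixed point each
  cycle feeds QT0\* + b<sub>k</sub>·τ0 units of x1/x2 into the environment
  while consumption is QT02\*; for the shipped equilibrium preset the net is
  +11861 units per cycle, so the pools indeed diverge. Qx\* is reported as
  the *pre-competition* pool at generalist operation times (post-competition
  free x is zero in the scarce regime).

Equilibria with surviving specialists are out of scope: the simulations show
only aperiodic fluctuation there, and no such fixed point is analyzed.

## What the presets emulate — and what they do not

The presets are the published computer-experiment configurations themselves
(horizon 200, the printed rates, clocks and initial densities); they are the
study conditions, not synthetic approximations, and the suite asserts their
outcomes: competitive exclusion vs. the focal specialist's initial density,
the keystone role of the generalist, the joint fate of equal-clock
specialists, the non-monotone survival "anomaly" in the decay-rate sweep,
and mean densities tracking the x inflow. Passing these says nothing about
regimes the experiments do not visit — e.g. very long horizons (the
b1 = b2 = −1000 anomaly run classifies T2 at its last operation before
t = 200, after its collapse near t ≈ 151), more than three species, or
stochastic (non-expected-value) sharing.

## Known limitations

* Cases II–VII are realized through the generalized competition operator,
  not from an independently published per-case formula set; the one-species
  equivalence and the conservation invariant are the evidence for the
  generalization.
* Default nutrient bookkeeping is (deliberately) not mass-conserving for the
  parental units of failed young; see the flag above.
* The extinction threshold is a classification device; trajectories that
  hover just above ε for the whole horizon are reported as survivors.
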