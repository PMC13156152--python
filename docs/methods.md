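# Methods

## Model

The package implements a capacitated, bi-objective integer location-allocation
model over a set of municipalities that act both as demand nodes (I) and as
candidate center sites (J), with two intervention types K = {prevention,
mitigation}. Decision variables are integer patient flows `Y[i,j,k]`, integer
annual capacity hours `C[j,k]`, and binary openings `X[j]`. Both objectives
are maximized:

* **OF1 (risk + proximity)** weights the served patients by their town's
  composite risk index `R[i,k]` (weight δ) against the normalized negative
  travel distance `−d_ij/d_max` (weight 1−δ).
* **OF2 (equity + proximity)** replaces risk by the equity index
  `σ[i,k] = RP·MPI` (halved for mitigation) with weight π.

Constraints: per-node-per-intervention demand caps; per-intervention budgets
on funded hours (`F[k]·ΣC ≤ B[k]`); a minimum viable size for any open center
(`Σ_k C[j,k] ≥ R_min·X[j]`); service-time capacity (`L[k]·Σ_i Y ≤ C[j,k]`);
a big-M link closing flows at unopened sites (M defaults to the total
demand, the tightest value that never cuts a feasible flow); and a
minimum-care floor of φ patients per town summed over interventions (an
optional per-intervention floor `phi_k` is available). An explicit closure
link `C[j,k] ≤ floor(B[k]/F[k])·X[j]` keeps capacity at zero for closed
sites; without it the budget could be consumed by phantom capacity at sites
that never open.

### Model assumptions worth knowing

* The composite indices treat absent signals as zero: a town with no
  social-media posts anywhere gets ψ = 0, which understates risk in towns
  with little online activity. The same all-zero convention applies to
  consumers and incidents so degenerate inputs stay runnable.
* The mitigation risk and equity indices are exactly half their prevention
  counterparts (`R² = R¹/2`, `σ² = σ¹/2`). The package implements the
  formulas as stated even though the accompanying verbal ratio (two at
  mitigation risk per one at prevention risk) could be read the other way.
* Funded capacity is costless in the objectives; only the budget constrains
  it. A consequence: whenever total fundable hours exceed `n·R_min`, opening
  more centers is weakly objective-improving (shorter distances), so the
  number of open centers is governed by `floor(total fundable hours/R_min)`
  and not by demand volume. The synthetic default conditions put that ratio
  at 2–3, producing the budget-limited few-center regime.

## Exact solving

`scipy.optimize.milp` (HiGHS branch-and-bound) solves each scalarized
problem at a relative optimality gap of 1e-4 (configurable). Two
tightenings are added that do not change the integer feasible set but make
the LP relaxation far stronger: disaggregated opening links
`Y[i,j,k] ≤ D[i,k]·X[j]` and the valid cut
`Σ_j X[j] ≤ floor(total fundable hours / R_min)`. At the default 23-node
scale these cut equity-objective solve times from ~25 s to ~1.5 s. All
objective values attached to solutions are recomputed from the flow matrix,
never read back from the solver, and `verify_solution` re-checks every
inequality on every solution the package emits.

An exhaustive enumeration oracle (`brute_force_solve`) provides an
independent optimum for testing. It is guarded to |J| ≤ 3 and total demand
≤ 12, enumerates every open pattern and integer flow assignment, and checks
budget/minimum-hours feasibility by a counting argument (extra hours needed
to reach `R_min` at open sites may draw on either budget, so feasibility
reduces to comparing totals). It shares only the objective-evaluation
helpers with the MILP path.

## Frontier and knee

The ε-constraint sweep maximizes OF1 subject to `OF2 ≥ ε` on a linear grid
between the OF2 value at the unconstrained OF1 optimum and the OF2 optimum
— exactly the trade-off range (the converse sweep is available via
`direction="of2"`). Each floor is relaxed by 1e-6 so a bound produced by a
gap-limited solve remains attainable; infeasible ε values are logged and
skipped, dominated and duplicate points filtered, and points sorted by ε.

Knee selection standardizes each objective by the mean and *population*
standard deviation over the frontier points only (the ideal point is
transformed with the same statistics, not pooled into them), then picks the
point of minimum Euclidean distance to the standardized ideal; ties go to
the lowest index, a single point is returned untransformed, and a
zero-variance objective contributes nothing to the distance. This makes the
selection invariant under positive affine rescaling of either objective.

## Baseline heuristic

The population-ranked baseline opens centers in descending population order
(ties by node id). Each opened site absorbs the smaller of the remaining
per-intervention budget hours and the hours its *own* municipality's full
demand would need, padded up to `R_min` from whichever budget has slack;
opening stops when the remaining budgets cannot fund another minimum-size
center. This per-site absorption cap is the design choice that makes both
limiting regimes come out right: a dominant city whose own demand exceeds
the whole budget absorbs everything (a single center), while an ample
budget opens every site. Flows are assigned in two passes — every node
first receives its φ minimum from the nearest open center with spare hours
(cheaper prevention hours first), then each center's residual capacity
serves its own town's remaining demand. The result always passes
`verify_solution`, so its objective values are valid lower bounds on the
exact optima (asserted in tests).

## Coverage and projections

Coverage within a radius (default 40 km, inclusive boundary) divides the
patients served by in-radius centers by the node's *demand*, not by
patients served — unmet demand counts against coverage. Per-intervention
averages are unweighted means over nodes, and the overall figure is the
mean of the two averages. The expansion projection is deliberately
back-of-envelope: the overall figure splits evenly over existing centers
(per-center share quoted at two decimals), an extra center adds one share,
and a capacity multiplier scales the whole baseline; the headline is
rounded to the nearest integer percent, with the unrounded value returned
alongside.

## Synthetic networks

The generator emulates the structure of a coastal department with one
dominant capital: ~23 municipalities; log-normal town sizes with the
capital forced to ~60% of the total population; posts per capita with a 5×
multiplier for the capital (so it holds the large majority of posts, as the
observed post distribution does); Poisson incidents; poverty and rurality
sampled to fall with population rank; mitigation demand equal to the
estimated consumer count with prevention demand at half of it (the
two-to-one mitigation:prevention structure of the risk assumption); and
per-intervention budgets at 30% of the full-service cost, doubled (and
logged) in the rare draws where they cannot fund the minimum-care load plus
one minimum-size center. Default scalars are the study conditions: δ = π =
0.7, L = (0.05, 1.0) h/patient (20-person prevention groups, individual
one-hour mitigation sessions), R_min = 2080 h (8 h × 260 d), hourly costs
derived from monthly salaries of 1.8 M and 6.1 M COP at 160 h/month, φ = 5
patients. Seeds are mandatory; a fixed seed reproduces byte-identical
profiles.

What the generator does *not* emulate: driving-time road networks
(distances are haversine great circles), spatial autocorrelation of poverty
beyond the population-rank link, demand uncertainty, and any real survey
microdata. Passing tests therefore demonstrate correctness of the method
and its qualitative behavior (risk-vs-equity conflict, dominant-city
baseline pathology), not calibrated predictions for a real department.

`atlantico_fixture` builds a 23-town instance named after the real
municipalities and carrying every published scalar — budgets 654 M COP
(prevention) and 3,000 M COP (mitigation), the salary-derived hourly costs,
L, R_min, δ = π = 0.7, and the published per-town post totals (multi-town
rows split evenly with the remainder to the first-listed town; each town
total split deterministically into a majority-negative sentiment mix so the
published totals stay exact). Populations, demands, poverty, rurality,
incidents and coordinates are synthetic stand-ins from a fixed seed; demand
is scaled so the published budgets fund about a third of the required
service hours, making the budget genuinely bind. The fixture must not be
read as the real department, and no reference quantity depends on its
synthetic fields.

## Problem sizes and numerical choices

Tests run the full 20-point ε sweep at the 23-node study scale once
(shared fixture); randomized structural checks (heuristic dominance across
10 seeds, budget monotonicity across 5 seeds) use 8–10-node networks, and
the enumeration-oracle comparisons use 2–3-node instances inside the
oracle's guard. Comparisons of "optimal" values allow slack consistent with
the 1e-4 solver gap (`1e-6 + 1e-4·|value|`); oracle-vs-solver equalities on
tiny instances are asserted at 1e-9. The published coverage worked example
averages 14.06% and 35.29% to 24.675, quoted as 24.67 (truncation); the
package asserts agreement at the printed precision rather than reproducing
the truncation rule.

## Known limitations

* No routing: distance realism is limited to great circles unless a driving
  matrix is supplied via CSV.
* Single-period, deterministic demand; no congestion or usage feedback (a
  dominant-city center may be overwhelmed in practice).
* The per-intervention budget split of the baseline heuristic is applied
  independently per intervention; how a real planner would pool budgets is
  not modeled.
* γ is a raw cross-town incident share, not per-capita; a per-capita
  variant would change the risk ranking of large towns.
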