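"""The capacitated bi-objective integer program and its exact solver.

Decision variables, all integer:

* ``Y[i, j, k]`` — patients from demand node *i* served at site *j* under
  intervention *k* (k=1 prevention, k=2 mitigation; array index 0/1),
* ``C[j, k]``    — annual capacity hours funded at site *j* for *k*,
* ``X[j]``       — binary: site *j* opens a center.

Objectives (both maximized):

* OF1 = delta * sum R[i,k] Y[i,j,k]  + (1-delta) * sum (-d_ij/d_max) Y[i,j,k]
* OF2 = pi    * sum sigma[i,k] Y[i,j,k] + (1-pi)  * sum (-d_ij/d_max) Y[i,j,k]

Constraints:

* demand:        sum_j Y[i,j,k] <= D[i,k]                 for all i, k
* budget:        F[k] * sum_j C[j,k] <= budget[k]          for all k
* minimum hours: sum_k C[j,k] >= r_min * X[j]              for all j
* service time:  L[k] * sum_i Y[i,j,k] <= C[j,k]           for all j, k
* big-M link:    sum_{i,k} Y[i,j,k] <= big_m * X[j]        for all j
* minimum care:  sum_{j,k} Y[i,j,k] >= phi                 for all i
* closure link:  C[j,k] <= floor(budget[k]/F[k]) * X[j]    for all j, k

The closure link is not printed in the classical statement of the model but
is required for its narrative to hold: without it a closed site could carry
phantom capacity that consumes budget.  ``big_m`` defaults to the total
demand, the tightest value that never cuts a feasible flow.

Solving is exact branch-and-bound via ``scipy.optimize.milp`` (HiGHS) at a
configurable relative optimality gap (default 1e-4).  Objective values on
returned solutions are always recomputed from the flow matrix, never read
back from the solver.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import InfeasibleError, InputError, SolverError
from .geo import DistanceMatrix

__all__ = [
    "ProblemInstance",
    "SolutionAllocation",
    "default_big_m",
    "count_variables",
    "evaluate_of1",
    "evaluate_of2",
    "build_and_solve",
    "verify_solution",
    "brute_force_solve",
    "assemble_milp",
]

N_INTERVENTIONS = 2  # prevention (index 0), mitigation (index 1)


@dataclass
class ProblemInstance:
    """Fully parameterized model input.

    Attributes
    ----------
    demand_ids, site_ids : node identifier lists (sets I and J). In the
        municipality setting they coincide, but the model does not require it.
    R, sigma : (|I|, 2) risk and equity tables.
    D : (|I|, 2) integer demand table (patients).
    dm : DistanceMatrix whose rows/columns cover demand nodes and sites; the
        (i, j) block used is selected by id.
    budget, hourly_cost, hours_per_patient : per-intervention scalars
        (currency, currency/hour, hours/patient).
    r_min : minimum annual hours for an open center.
    phi : minimum patients served per demand node, summed over sites and
        interventions.
    phi_k : optional per-intervention minimum-care floors (length-2); when
        set, each node must additionally receive phi_k[k] patients of
        intervention k.
    big_m : flow bound at open sites; None means the total demand.
    delta, pi_weight : objective weights in [0, 1].
    mip_gap : relative optimality gap for the exact solver.
    """

    demand_ids: list[str]
    site_ids: list[str]
    R: np.ndarray
    sigma: np.ndarray
    D: np.ndarray
    dm: DistanceMatrix
    budget: np.ndarray
    hourly_cost: np.ndarray
    hours_per_patient: np.ndarray
    r_min: float = 2080.0
    phi: int = 0
    phi_k: np.ndarray | None = None
    big_m: float | None = None
    delta: float = 0.7
    pi_weight: float = 0.7
    mip_gap: float = 1e-4

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.D = np.asarray(self.D, dtype=int)
        for name in ("budget", "hourly_cost", "hours_per_patient"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        nI, nJ = len(self.demand_ids), len(self.site_ids)
        if nI < 1 or nJ < 1:
            raise InputError("need at least one demand node and one site")
        nK = self.n_interventions
        for name, arr in (("R", self.R), ("sigma", self.sigma), ("D", self.D)):
            if arr.shape != (nI, nK):
                raise InputError(f"{name} must have shape ({nI}, {nK}), "
                                 f"got {arr.shape}")
            if np.any(arr < 0):
                raise InputError(f"{name} must be nonnegative")
        for name in ("budget", "hourly_cost", "hours_per_patient"):
            if getattr(self, name).shape != (nK,):
                raise InputError(f"{name} must have shape ({nK},)")
        if np.any(self.hours_per_patient <= 0):
            raise InputError("hours_per_patient must be positive")
        if np.any(self.budget < 0):
            raise InputError("budget must be nonnegative")
        if not (0.0 <= self.delta <= 1.0 and 0.0 <= self.pi_weight <= 1.0):
            raise InputError("delta and pi_weight must lie in [0, 1]")
        if self.phi_k is not None:
            self.phi_k = np.asarray(self.phi_k, dtype=int)
            if self.phi_k.shape != (nK,) or np.any(self.phi_k < 0):
                raise InputError("phi_k must be a nonnegative length-2 vector")
        pos = {nid: k for k, nid in enumerate(self.dm.node_ids)}
        try:
            self._rows = [pos[i] for i in self.demand_ids]
            self._cols = [pos[j] for j in self.site_ids]
        except KeyError as exc:
            raise InputError(f"node {exc.args[0]!r} missing from distance "
                             "matrix") from exc

    # -- derived quantities -------------------------------------------------

    @property
    def n_interventions(self) -> int:
        return N_INTERVENTIONS

    @property
    def distances(self) -> np.ndarray:
        """(|I|, |J|) km block of the distance matrix."""
        return self.dm.d[np.ix_(self._rows, self._cols)]

    @property
    def d_max(self) -> float:
        return self.dm.d_max

    def normalized_distances(self) -> np.ndarray:
        dmax = self.d_max
        dist = self.distances
        if dmax == 0.0:
            if np.any(dist > 0):
                raise InputError("d_max is zero but distances are nonzero")
            return np.zeros_like(dist)
        return dist / dmax

    def effective_big_m(self) -> float:
        return float(self.D.sum()) if self.big_m is None else float(self.big_m)

    def capacity_caps(self) -> np.ndarray:
        """Max fundable integer hours per intervention: floor(budget/F)."""
        with np.errstate(divide="ignore"):
            caps = np.floor(self.budget / self.hourly_cost)
        return np.where(np.isfinite(caps), caps, 0.0).astype(int)


@dataclass
class SolutionAllocation:
    """One feasible (or optimal) allocation with both objective values."""

    Y: np.ndarray          # (|I|, |J|, 2) integer patient flows
    C: np.ndarray          # (|J|, 2) integer capacity hours
    X: np.ndarray          # (|J|,) binary open indicators
    of1: float
    of2: float
    solver_status: str     # "optimal" | "gap-limited" | "heuristic"
    gap: float = 0.0

    @property
    def open_sites(self) -> np.ndarray:
        return np.flatnonzero(self.X > 0)


def default_big_m(instance: ProblemInstance) -> float:
    """Sum of the total demand — the recommended practical big-M."""
    return float(instance.D.sum())


def count_variables(n_demand: int, n_sites: int,
                    n_interventions: int) -> tuple[int, int]:
    """Total integer variables (flows + capacities + open flags) and binaries.

    At 23 demand nodes, 23 sites and 2 interventions this gives
    (1127, 23): 1058 flow + 46 capacity + 23 binary open variables.
    """
    if min(n_demand, n_sites, n_interventions) < 1:
        raise InputError("set sizes must be positive")
    total = (n_demand * n_sites * n_interventions
             + n_sites * n_interventions + n_sites)
    return total, n_sites


def _objective_coeffs(instance: ProblemInstance, which: str) -> np.ndarray:
    """Per-flow coefficients of OF1 or OF2 as an (|I|, |J|, 2) array."""
    ndist = instance.normalized_distances()  # (nI, nJ)
    if which == "of1":
        w, table = instance.delta, instance.R
    elif which == "of2":
        w, table = instance.pi_weight, instance.sigma
    else:
        raise InputError(f"unknown objective {which!r}")
    # w * table[i,k] - (1-w) * d_ij/d_max, broadcast to (nI, nJ, nK)
    return (w * table[:, None, :]
            - (1.0 - w) * ndist[:, :, None])


def _flow_value(instance: ProblemInstance, Y: np.ndarray, which: str) -> float:
    Y = np.asarray(Y, dtype=float)
    nI, nJ = len(instance.demand_ids), len(instance.site_ids)
    if Y.shape != (nI, nJ, N_INTERVENTIONS):
        raise InputError(f"Y must have shape ({nI}, {nJ}, {N_INTERVENTIONS})")
    if np.any(Y < 0):
        raise InputError("flows must be nonnegative")
    return float(np.sum(_objective_coeffs(instance, which) * Y))


def evaluate_of1(instance: ProblemInstance, Y: np.ndarray) -> float:
    """Risk-and-distance objective of a flow matrix (independent of solver)."""
    return _flow_value(instance, Y, "of1")


def evaluate_of2(instance: ProblemInstance, Y: np.ndarray) -> float:
    """Equity-and-distance objective of a flow matrix."""
    return _flow_value(instance, Y, "of2")


# -- model assembly ---------------------------------------------------------

@dataclass
class _Layout:
    """Index layout of the flattened decision vector: Y block, C block, X."""
    nI: int
    nJ: int
    nK: int

    @property
    def n_y(self): return self.nI * self.nJ * self.nK

    @property
    def n_c(self): return self.nJ * self.nK

    @property
    def n(self): return self.n_y + self.n_c + self.nJ

    def y(self, i, j, k): return (i * self.nJ + j) * self.nK + k

    def c(self, j, k): return self.n_y + j * self.nK + k

    def x(self, j): return self.n_y + self.n_c + j


def assemble_milp(instance: ProblemInstance, objective: str = "of1",
                  epsilon_floor: float | None = None):
    """Assemble objective vector, constraints, bounds and integrality.

    Returns ``(c, constraints, bounds, integrality, layout)`` where ``c`` is
    the *maximization* coefficient vector (callers negate for scipy).
    """
    nI, nJ, nK = len(instance.demand_ids), len(instance.site_ids), N_INTERVENTIONS
    lay = _Layout(nI, nJ, nK)
    big_m = instance.effective_big_m()
    caps = instance.capacity_caps()
    L = instance.hours_per_patient
    F = instance.hourly_cost

    c = np.zeros(lay.n)
    c[:lay.n_y] = _objective_coeffs(instance, objective).ravel()

    rows, cols, vals, lb, ub = [], [], [], [], []

    def add_row(idx_val_pairs, lo, hi):
        r = len(lb)
        for idx, v in idx_val_pairs:
            rows.append(r); cols.append(idx); vals.append(v)
        lb.append(lo); ub.append(hi)

    # demand: sum_j Y[i,j,k] <= D[i,k]
    for i in range(nI):
        for k in range(nK):
            add_row([(lay.y(i, j, k), 1.0) for j in range(nJ)],
                    -np.inf, float(instance.D[i, k]))
    # budget: F[k] sum_j C[j,k] <= budget[k]
    for k in range(nK):
        add_row([(lay.c(j, k), float(F[k])) for j in range(nJ)],
                -np.inf, float(instance.budget[k]))
    # minimum hours: sum_k C[j,k] - r_min X[j] >= 0
    for j in range(nJ):
        add_row([(lay.c(j, k), 1.0) for k in range(nK)]
                + [(lay.x(j), -float(instance.r_min))], 0.0, np.inf)
    # service time: L[k] sum_i Y[i,j,k] - C[j,k] <= 0
    for j in range(nJ):
        for k in range(nK):
            add_row([(lay.y(i, j, k), float(L[k])) for i in range(nI)]
                    + [(lay.c(j, k), -1.0)], -np.inf, 0.0)
    # big-M link: sum_{i,k} Y[i,j,k] - M X[j] <= 0
    for j in range(nJ):
        add_row([(lay.y(i, j, k), 1.0)
                 for i in range(nI) for k in range(nK)]
                + [(lay.x(j), -big_m)], -np.inf, 0.0)
    # disaggregated links Y[i,j,k] <= D[i,k] X[j]: implied at integer points
    # by the demand and big-M rows, but far tighter in the LP relaxation
    for j in range(nJ):
        for i in range(nI):
            for k in range(nK):
                if instance.D[i, k] > 0:
                    add_row([(lay.y(i, j, k), 1.0),
                             (lay.x(j), -float(instance.D[i, k]))],
                            -np.inf, 0.0)
    # minimum care: sum_{j,k} Y[i,j,k] >= phi
    for i in range(nI):
        add_row([(lay.y(i, j, k), 1.0)
                 for j in range(nJ) for k in range(nK)],
                float(instance.phi), np.inf)
    # optional per-intervention minimum-care floors
    if instance.phi_k is not None:
        for i in range(nI):
            for k in range(nK):
                if instance.phi_k[k] > 0:
                    add_row([(lay.y(i, j, k), 1.0) for j in range(nJ)],
                            float(instance.phi_k[k]), np.inf)
    # closure link: C[j,k] - caps[k] X[j] <= 0
    for j in range(nJ):
        for k in range(nK):
            add_row([(lay.c(j, k), 1.0), (lay.x(j), -float(caps[k]))],
                    -np.inf, 0.0)
    # valid cut: minimum-hours floors and the budgets jointly cap the number
    # of open centers at floor(total fundable hours / r_min)
    if instance.r_min > 0:
        max_open = int(caps.sum() // instance.r_min)
        if max_open < nJ:
            add_row([(lay.x(j), 1.0) for j in range(nJ)],
                    -np.inf, float(max_open))
    # epsilon floor on the other objective
    if epsilon_floor is not None:
        other = "of2" if objective == "of1" else "of1"
        coeffs = _objective_coeffs(instance, other).ravel()
        add_row([(idx, float(v)) for idx, v in enumerate(coeffs) if v != 0.0],
                float(epsilon_floor), np.inf)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(lb), lay.n))
    constraints = LinearConstraint(A, np.array(lb), np.array(ub))

    var_lb = np.zeros(lay.n)
    var_ub = np.empty(lay.n)
    # Y bounded by its node demand, C by the budget cap, X binary
    ubY = np.broadcast_to(instance.D[:, None, :].astype(float),
                          (nI, nJ, nK)).ravel()
    var_ub[:lay.n_y] = ubY
    var_ub[lay.n_y:lay.n_y + lay.n_c] = np.tile(caps.astype(float), nJ)
    var_ub[lay.n_y + lay.n_c:] = 1.0
    bounds = Bounds(var_lb, var_ub)
    integrality = np.ones(lay.n)
    return c, constraints, bounds, integrality, lay


def _necessary_condition_failure(instance: ProblemInstance,
                                 epsilon_floor: float | None) -> str | None:
    """Cheap checks that certify infeasibility before solving, or None."""
    if instance.phi_k is not None:
        for k in range(N_INTERVENTIONS):
            bad = np.flatnonzero(instance.D[:, k] < instance.phi_k[k])
            if len(bad):
                return (f"per-intervention floor phi_k[{k}]="
                        f"{instance.phi_k[k]} exceeds demand at node "
                        f"{instance.demand_ids[bad[0]]!r}")
    phi = instance.phi
    if phi > 0:
        totals = instance.D.sum(axis=1)
        bad = np.flatnonzero(totals < phi)
        if len(bad):
            i = bad[0]
            return (f"minimum-care level phi={phi} exceeds total demand "
                    f"{totals[i]} at node {instance.demand_ids[i]!r}")
        caps = instance.capacity_caps()
        if caps.sum() < instance.r_min:
            return (f"budgets fund at most {caps.sum()} capacity hours, "
                    f"below the r_min={instance.r_min} needed to open any "
                    "center while phi > 0 requires service")
        # cheapest way to serve phi*|I| patients uses the smaller L first
        need = phi * len(instance.demand_ids)
        hours_avail = caps.astype(float)
        served = 0.0
        for k in np.argsort(instance.hours_per_patient):
            served += hours_avail[k] / instance.hours_per_patient[k]
        if served < need:
            return (f"budgets can serve at most {served:.0f} patients, below "
                    f"the phi*|I| = {need} minimum-care requirement")
    return None


def build_and_solve(instance: ProblemInstance, objective: str = "of1",
                    epsilon_floor: float | None = None,
                    mip_gap: float | None = None,
                    time_limit: float | None = None) -> SolutionAllocation:
    """Solve the model exactly for one objective, optionally floor-constrained.

    Parameters
    ----------
    objective : "of1" (risk) or "of2" (equity).
    epsilon_floor : if given, the *other* objective is constrained >= floor
        (the epsilon-constraint scalarization).
    mip_gap : relative optimality gap; defaults to ``instance.mip_gap``.

    Raises
    ------
    InfeasibleError
        naming the first violated necessary condition when identifiable.
    """
    reason = _necessary_condition_failure(instance, epsilon_floor)
    if reason is not None:
        raise InfeasibleError(reason)
    c, constraints, bounds, integrality, lay = assemble_milp(
        instance, objective, epsilon_floor)
    options = {"mip_rel_gap": instance.mip_gap if mip_gap is None else mip_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(c=-c, constraints=constraints, bounds=bounds,
               integrality=integrality, options=options)
    if res.status == 2:
        if epsilon_floor is not None:
            raise InfeasibleError(
                f"no allocation attains the epsilon floor {epsilon_floor!r} "
                "on the constrained objective")
        raise InfeasibleError("solver certified the model infeasible")
    if res.x is None:
        raise SolverError(f"MILP backend failed: {res.message}")
    x = np.rint(res.x).astype(int)
    Y = x[:lay.n_y].reshape(lay.nI, lay.nJ, lay.nK)
    C = x[lay.n_y:lay.n_y + lay.n_c].reshape(lay.nJ, lay.nK)
    X = x[lay.n_y + lay.n_c:]
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    status = "optimal" if res.status == 0 else "gap-limited"
    return SolutionAllocation(
        Y=Y, C=C, X=X,
        of1=evaluate_of1(instance, Y),
        of2=evaluate_of2(instance, Y),
        solver_status=status, gap=gap)


def verify_solution(instance: ProblemInstance,
                    solution: SolutionAllocation) -> list[str]:
    """Re-check every model inequality on a solution; empty list iff clean.

    Solver output is never trusted: this runs on every solution the package
    produces, exact or heuristic.
    """
    v: list[str] = []
    Y, C, X = solution.Y, solution.C, solution.X
    nI, nJ = len(instance.demand_ids), len(instance.site_ids)
    if Y.shape != (nI, nJ, N_INTERVENTIONS) or C.shape != (nJ, N_INTERVENTIONS):
        return [f"shape mismatch: Y {Y.shape}, C {C.shape}"]
    if np.any(Y < 0) or np.any(C < 0):
        v.append("negative flow or capacity")
    if np.any(np.rint(Y) != Y) or np.any(np.rint(C) != C):
        v.append("non-integer flow or capacity")
    if np.any((X != 0) & (X != 1)):
        v.append("open indicator not binary")
    L, F = instance.hours_per_patient, instance.hourly_cost
    for i in range(nI):
        for k in range(N_INTERVENTIONS):
            if Y[i, :, k].sum() > instance.D[i, k]:
                v.append(f"demand exceeded at node "
                         f"{instance.demand_ids[i]!r}, "
                         f"intervention {k + 1}")
    for k in range(N_INTERVENTIONS):
        if F[k] * C[:, k].sum() > instance.budget[k] + 1e-6:
            v.append(f"budget exceeded for intervention {k + 1}")
    for j in range(nJ):
        if C[j].sum() < instance.r_min * X[j] - 1e-9:
            v.append(f"minimum-hours floor violated at open site "
                     f"{instance.site_ids[j]!r}")
        if X[j] == 0 and C[j].sum() > 0:
            v.append(f"capacity without opening at site "
                     f"{instance.site_ids[j]!r}")
        for k in range(N_INTERVENTIONS):
            if L[k] * Y[:, j, k].sum() > C[j, k] + 1e-9:
                v.append(f"service time exceeds capacity at site "
                         f"{instance.site_ids[j]!r}, intervention {k + 1}")
        if Y[:, j, :].sum() > instance.effective_big_m() * X[j]:
            v.append(f"flow at closed site {instance.site_ids[j]!r}")
    for i in range(nI):
        if Y[i].sum() < instance.phi:
            v.append(f"minimum-care floor unmet at node "
                     f"{instance.demand_ids[i]!r}")
        if instance.phi_k is not None:
            for k in range(N_INTERVENTIONS):
                if Y[i, :, k].sum() < instance.phi_k[k]:
                    v.append(f"per-intervention minimum-care floor unmet at "
                             f"node {instance.demand_ids[i]!r}, "
                             f"intervention {k + 1}")
    return v


# -- enumeration oracle ------------------------------------------------------

_BF_MAX_SITES = 3
_BF_MAX_DEMAND = 12
_BF_MAX_COMBOS = 2_000_000


def _allocations(total: int, m: int):
    """All nonneg integer m-vectors with sum <= total (lexicographic)."""
    if m == 0:
        yield ()
        return
    for first in range(total + 1):
        for rest in _allocations(total - first, m - 1):
            yield (first,) + rest


def brute_force_solve(instance: ProblemInstance, objective: str = "of1",
                      epsilon_floor: float | None = None
                      ) -> SolutionAllocation:
    """Exact optimum by exhaustive enumeration — the independent test oracle.

    Enumerates every open-site pattern and every integer flow assignment to
    open sites, checking budget, minimum-hours and minimum-care feasibility
    directly.  Guarded to tiny instances (|J| <= 3, |K| <= 2, total demand
    <= 12); refuses to run beyond the guard.  Ties are broken by enumeration
    order (open patterns in binary counting order, flows lexicographically),
    so only objective values are comparable with the MILP solver.
    """
    nI, nJ, nK = len(instance.demand_ids), len(instance.site_ids), N_INTERVENTIONS
    total_D = int(instance.D.sum())
    if nJ > _BF_MAX_SITES or total_D > _BF_MAX_DEMAND:
        raise InputError(
            f"brute-force guard exceeded: |J|={nJ} (max {_BF_MAX_SITES}), "
            f"total demand {total_D} (max {_BF_MAX_DEMAND})")
    caps = instance.capacity_caps()
    L = instance.hours_per_patient
    r_min = instance.r_min
    phi = instance.phi
    coeffs = _objective_coeffs(instance, objective)
    other_coeffs = (_objective_coeffs(
        instance, "of2" if objective == "of1" else "of1")
        if epsilon_floor is not None else None)

    best_val = -math.inf
    best = None
    for pattern in itertools.product((0, 1), repeat=nJ):
        open_j = [j for j in range(nJ) if pattern[j]]
        m = len(open_j)
        # per-(i,k) flow options to open sites
        cells = []
        n_combos = 1
        for i in range(nI):
            for k in range(nK):
                opts = list(_allocations(int(instance.D[i, k]), m))
                cells.append(((i, k), opts))
                n_combos *= len(opts)
                if n_combos > _BF_MAX_COMBOS:
                    raise InputError("brute-force enumeration too large")
        for combo in itertools.product(*(opts for _, opts in cells)):
            Y = np.zeros((nI, nJ, nK), dtype=int)
            for ((i, k), _), alloc in zip(cells, combo):
                for pos, j in enumerate(open_j):
                    Y[i, j, k] = alloc[pos]
            if phi > 0 and np.any(Y.sum(axis=(1, 2)) < phi):
                continue
            if instance.phi_k is not None and np.any(
                    Y.sum(axis=1) < instance.phi_k[None, :]):
                continue
            # minimal integer capacity hours needed per (j, k)
            base = np.zeros((nJ, nK), dtype=int)
            for j in open_j:
                for k in range(nK):
                    base[j, k] = math.ceil(L[k] * Y[:, j, k].sum() - 1e-9)
            if np.any(base.sum(axis=0) > caps):
                continue
            # pad open sites up to r_min; extras may draw on either budget
            extras = sum(max(0, math.ceil(r_min - base[j].sum()))
                         for j in open_j)
            slack = (caps - base.sum(axis=0)).clip(min=0)
            if extras > slack.sum():
                continue
            val = float(np.sum(coeffs * Y))
            if other_coeffs is not None:
                if float(np.sum(other_coeffs * Y)) < epsilon_floor - 1e-9:
                    continue
            if val > best_val + 1e-12:
                C = base.copy()
                rem = slack.astype(int).copy()
                for j in open_j:
                    need = max(0, math.ceil(r_min - C[j].sum()))
                    for k in np.argsort(-rem):
                        take = min(need, rem[k])
                        C[j, k] += take
                        rem[k] -= take
                        need -= take
                best_val = val
                best = (Y, C, np.array(pattern, dtype=int))
    if best is None:
        raise InfeasibleError("exhaustive enumeration found no feasible "
                              "allocation")
    Y, C, X = best
    return SolutionAllocation(
        Y=Y, C=C, X=X,
        of1=evaluate_of1(instance, Y),
        of2=evaluate_of2(instance, Y),
        solver_status="optimal", gap=0.0)
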