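"""Epsilon-constraint Pareto frontier generation and knee-point selection.

The bi-objective model is scalarized by maximizing the risk objective (OF1)
subject to a floor ``OF2 >= epsilon`` swept over a linear grid between the
OF2 value of the unconstrained OF1 optimum and the OF2 optimum (the
trade-off range).  The converse sweep (maximize OF2, floor OF1) is available
via ``direction="of2"``.

The recommended compromise is the frontier point closest to the *ideal
point* (the two independently attained optima) in z-score-standardized
objective space: each objective is centred and scaled by its mean and
population standard deviation over the frontier points, the ideal point is
transformed with the same statistics, and the point of minimum Euclidean
distance wins (ties to the lowest index).  A zero-variance objective
contributes nothing to the distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleError, InputError
from .optmodel import ProblemInstance, SolutionAllocation, build_and_solve

__all__ = ["ParetoPoint", "ParetoFrontier", "ideal_point", "epsilon_sweep",
           "filter_nondominated", "select_knee"]

log = logging.getLogger(__name__)

#: absolute slack subtracted from each epsilon floor so that the floor value
#: produced by a gap-limited solve remains attainable
_FLOOR_SLACK = 1e-6


@dataclass
class ParetoPoint:
    epsilon: float
    of1: float
    of2: float
    solution: SolutionAllocation


@dataclass
class ParetoFrontier:
    points: list[ParetoPoint]          # non-dominated, sorted by epsilon
    ideal: tuple[float, float]         # (OF1*, OF2*)
    knee: int                          # index into points
    epsilon_grid: list[float]
    skipped: list[float] = field(default_factory=list)

    @property
    def knee_point(self) -> ParetoPoint:
        return self.points[self.knee]

    def to_frame(self) -> pd.DataFrame:
        """Frontier table: epsilon, of1, of2, n_open_sites, open_site_ids."""
        rows = []
        for t, p in enumerate(self.points):
            open_idx = p.solution.open_sites
            rows.append({
                "epsilon": p.epsilon, "of1": p.of1, "of2": p.of2,
                "n_open_sites": int(len(open_idx)),
                "open_site_ids": ";".join(str(j) for j in open_idx),
                "is_knee": t == self.knee,
            })
        return pd.DataFrame(rows)


def ideal_point(instance: ProblemInstance, **solve_kw) -> tuple[float, float]:
    """(OF1*, OF2*): each objective maximized independently."""
    s1 = build_and_solve(instance, "of1", **solve_kw)
    s2 = build_and_solve(instance, "of2", **solve_kw)
    return s1.of1, s2.of2


def filter_nondominated(points):
    """Keep maximal points of a list of (of1, of2) pairs; collapse duplicates.

    A point is dropped when another has both coordinates at least as large
    with one strictly larger, or is an exact duplicate appearing earlier.
    Returns the retained points in input order.
    """
    pts = [tuple(map(float, p)) for p in points]
    keep = []
    seen = set()
    for a in pts:
        if a in seen:
            continue
        dominated = any(
            b[0] >= a[0] and b[1] >= a[1] and b != a for b in pts)
        if not dominated:
            keep.append(a)
            seen.add(a)
    return keep


def select_knee(frontier_points, ideal: tuple[float, float]) -> int:
    """Index of the frontier point nearest the ideal in z-scored space.

    ``frontier_points`` is a sequence of (of1, of2) pairs.  Standardization
    uses the mean and population standard deviation of the frontier points
    only; the ideal point is transformed with those same statistics.
    """
    pts = np.asarray([(p[0], p[1]) for p in frontier_points], dtype=float)
    if len(pts) == 0:
        raise InputError("cannot select a knee on an empty frontier")
    if len(pts) == 1:
        return 0
    mean = pts.mean(axis=0)
    std = pts.std(axis=0)  # population form
    z = np.zeros_like(pts)
    z_ideal = np.zeros(2)
    for c in range(2):
        if std[c] > 0:
            z[:, c] = (pts[:, c] - mean[c]) / std[c]
            z_ideal[c] = (ideal[c] - mean[c]) / std[c]
        # zero-variance coordinate contributes 0 to every distance
    dist = np.linalg.norm(z - z_ideal, axis=1)
    return int(np.argmin(dist))


def epsilon_sweep(instance: ProblemInstance, n_points: int = 20,
                  grid=None, direction: str = "of1",
                  **solve_kw) -> ParetoFrontier:
    """Trace the Pareto frontier with the epsilon-constraint method.

    Parameters
    ----------
    n_points : size of the linear epsilon grid (>= 2) when ``grid`` is None.
    grid : explicit list of epsilon values overriding the linear grid.
    direction : "of1" maximizes OF1 with OF2 floored (default); "of2" the
        converse.

    Infeasible or failed epsilon values are logged and recorded in
    ``skipped``; an entirely infeasible grid raises ``InfeasibleError``.
    """
    if direction not in ("of1", "of2"):
        raise InputError(f"direction must be 'of1' or 'of2', got {direction!r}")
    primary, floored = (("of1", "of2") if direction == "of1"
                        else ("of2", "of1"))
    s_primary = build_and_solve(instance, primary, **solve_kw)
    s_floored = build_and_solve(instance, floored, **solve_kw)

    def val(sol: SolutionAllocation, which: str) -> float:
        return sol.of1 if which == "of1" else sol.of2

    lo = val(s_primary, floored)   # floored objective at the primary optimum
    hi = val(s_floored, floored)   # floored objective's own optimum
    if grid is None:
        if n_points < 2:
            raise InputError("n_points must be at least 2")
        grid = list(np.linspace(lo, hi, n_points))
    else:
        grid = [float(e) for e in grid]

    points: list[ParetoPoint] = []
    skipped: list[float] = []
    for eps in grid:
        try:
            sol = build_and_solve(instance, primary,
                                  epsilon_floor=eps - _FLOOR_SLACK,
                                  **solve_kw)
        except InfeasibleError as exc:
            log.info("epsilon %.6g infeasible: %s", eps, exc)
            skipped.append(eps)
            continue
        points.append(ParetoPoint(eps, sol.of1, sol.of2, sol))
    if not points:
        raise InfeasibleError("every epsilon value in the grid was infeasible")

    retained_pairs = set(filter_nondominated([(p.of1, p.of2) for p in points]))
    seen = set()
    kept = []
    for p in sorted(points, key=lambda p: p.epsilon):
        pair = (p.of1, p.of2)
        if pair in retained_pairs and pair not in seen:
            kept.append(p)
            seen.add(pair)
    # (OF1*, OF2*) regardless of sweep direction
    ideal = ((s_primary if primary == "of1" else s_floored).of1,
             (s_primary if primary == "of2" else s_floored).of2)
    knee = select_knee([(p.of1, p.of2) for p in kept], ideal)
    return ParetoFrontier(points=kept, ideal=ideal, knee=knee,
                          epsilon_grid=list(grid), skipped=skipped)
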