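"""Coverage, capacity and sensitivity reporting.

Quantifies what an allocation delivers: the share of each node's demand
served by centers within a travel radius (default 40 km), per-center
capacity utilization, back-of-envelope expansion projections, and the two
sensitivity sweeps (objective weights, epsilon-grid resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InfeasibleError, InputError
from .geo import within_radius
from .indices import INTERVENTIONS
from .optmodel import (ProblemInstance, SolutionAllocation, build_and_solve,
                       N_INTERVENTIONS)

__all__ = ["CoverageReport", "coverage_report", "capacity_report",
           "scenario_projection", "weight_sweep", "epsilon_variation",
           "annual_hours", "hourly_cost", "allocation_table"]

log = logging.getLogger(__name__)


@dataclass
class CoverageReport:
    """Percent of demand served within a radius, per node and intervention."""

    per_node: pd.DataFrame        # node_id, coverage_prevention, coverage_mitigation
    averages: dict[str, float]    # unweighted mean per intervention
    overall: float                # mean of the two per-intervention averages
    radius_km: float


def coverage_report(instance: ProblemInstance, solution: SolutionAllocation,
                    radius_km: float = 40.0) -> CoverageReport:
    """Percent of each node's demand served by centers within the radius.

    The denominator is the node's demand (unserved demand counts against
    coverage); a zero-demand cell reports 0.  The radius test is inclusive
    (a center at exactly ``radius_km`` counts).  Per-intervention averages
    are unweighted means over nodes and the overall figure is the mean of
    the two averages.
    """
    mask = within_radius(instance.dm, radius_km)[
        np.ix_(instance._rows, instance._cols)]
    pct = np.zeros((len(instance.demand_ids), N_INTERVENTIONS))
    for k in range(N_INTERVENTIONS):
        served = (solution.Y[:, :, k] * mask).sum(axis=1)
        demand = instance.D[:, k]
        nz = demand > 0
        pct[nz, k] = 100.0 * served[nz] / demand[nz]
    per_node = pd.DataFrame({
        "node_id": instance.demand_ids,
        "coverage_prevention": pct[:, 0],
        "coverage_mitigation": pct[:, 1],
    })
    averages = {name: float(pct[:, k].mean())
                for k, name in enumerate(INTERVENTIONS)}
    overall = (averages["prevention"] + averages["mitigation"]) / 2.0
    return CoverageReport(per_node=per_node, averages=averages,
                          overall=overall, radius_km=radius_km)


def capacity_report(instance: ProblemInstance,
                    solution: SolutionAllocation) -> pd.DataFrame:
    """Capacity, patients, hours used and utilization per open site."""
    rows = []
    L = instance.hours_per_patient
    for j in solution.open_sites:
        for k, name in enumerate(INTERVENTIONS):
            cap = int(solution.C[j, k])
            patients = int(solution.Y[:, j, k].sum())
            used = float(L[k] * patients)
            rows.append({
                "site_id": instance.site_ids[j],
                "intervention": name,
                "capacity_hours": cap,
                "patients_served": patients,
                "hours_used": used,
                "utilization": used / cap if cap > 0 else 0.0,
            })
    return pd.DataFrame(rows, columns=["site_id", "intervention",
                                       "capacity_hours", "patients_served",
                                       "hours_used", "utilization"])


def allocation_table(instance: ProblemInstance,
                     solution: SolutionAllocation,
                     intervention: str) -> pd.DataFrame:
    """Node-by-open-center allocation: patients and professional hours."""
    k = list(INTERVENTIONS).index(intervention)
    rows = []
    for j in solution.open_sites:
        for i in range(len(instance.demand_ids)):
            y = int(solution.Y[i, j, k])
            if y > 0:
                rows.append({
                    "node_id": instance.demand_ids[i],
                    "site_id": instance.site_ids[j],
                    "patients": y,
                    "professional_hours":
                        float(instance.hours_per_patient[k] * y),
                })
    return pd.DataFrame(rows, columns=["node_id", "site_id", "patients",
                                       "professional_hours"])


def scenario_projection(overall_coverage_pct: float, n_extra_centers: int = 0,
                        capacity_multiplier: float = 1.0,
                        n_existing_centers: int = 2) -> tuple[float, int]:
    """Back-of-envelope coverage projection for network expansion.

    Assumes the existing overall coverage splits evenly over the existing
    centers (the per-center share is rounded to two decimals, as a planner
    would quote it); each additional center contributes one share, and
    scaling every center's capacity by ``capacity_multiplier`` scales the
    whole baseline.  Returns ``(projected_pct, headline_pct)`` where the
    headline is rounded to the nearest integer percent.
    """
    if overall_coverage_pct < 0 or n_extra_centers < 0 or capacity_multiplier < 0:
        raise InputError("projection inputs must be nonnegative")
    share = round(overall_coverage_pct / n_existing_centers, 2)
    projected = (overall_coverage_pct
                 + n_extra_centers * share
                 + (capacity_multiplier - 1.0) * overall_coverage_pct)
    return projected, int(round(projected))


def weight_sweep(instance: ProblemInstance, populations=None,
                 values=None, which: str = "both",
                 radius_km: float = 40.0, n_pareto_points: int = 10,
                 ) -> pd.DataFrame:
    """Re-solve across objective-weight settings and report coverage.

    ``which`` selects the weight(s) varied: "delta" re-solves the risk
    objective alone, "pi" the equity objective alone, "both" additionally
    traces a small frontier and reports its knee.  Infeasible rows are
    flagged and the sweep continues.
    """
    from dataclasses import replace
    from .pareto import epsilon_sweep

    if values is None:
        values = np.round(np.arange(0.1, 0.95, 0.1), 10)
    variants = {"delta": ["of1"], "pi": ["of2"],
                "both": ["of1", "of2", "knee"]}.get(which)
    if variants is None:
        raise InputError(f"which must be 'delta', 'pi' or 'both', got {which!r}")
    rows = []
    for w in values:
        inst = replace(instance)
        if which in ("delta", "both"):
            inst.delta = float(w)
        if which in ("pi", "both"):
            inst.pi_weight = float(w)
        for variant in variants:
            row = {"weight": float(w), "variant": variant, "feasible": True}
            try:
                if variant == "knee":
                    front = epsilon_sweep(inst, n_points=n_pareto_points)
                    sol = front.knee_point.solution
                else:
                    sol = build_and_solve(inst, variant)
                cov = coverage_report(inst, sol, radius_km)
                row.update(of1=sol.of1, of2=sol.of2,
                           overall_coverage=cov.overall,
                           n_open_sites=int(len(sol.open_sites)),
                           open_site_ids=";".join(
                               inst.site_ids[j] for j in sol.open_sites))
            except InfeasibleError as exc:
                log.info("weight %.2f variant %s infeasible: %s",
                         w, variant, exc)
                row["feasible"] = False
            rows.append(row)
    return pd.DataFrame(rows)


def epsilon_variation(frontier) -> float:
    """Max relative variation (%) of OF1 between consecutive frontier points.

    Accepts a ParetoFrontier or a sequence of OF1 values sorted by epsilon.
    Pairs whose leading value is zero are skipped.
    """
    if hasattr(frontier, "points"):
        of1 = [p.of1 for p in frontier.points]
    else:
        of1 = [float(v) for v in frontier]
    if len(of1) < 2:
        raise InputError("need at least two frontier points")
    best = 0.0
    for a, b in zip(of1, of1[1:]):
        if a == 0:
            continue
        best = max(best, 100.0 * abs(b - a) / abs(a))
    return best


def annual_hours(hours_per_day: float, days_per_year: float) -> float:
    """Annual service hours of one full-time professional."""
    if hours_per_day <= 0 or days_per_year <= 0:
        raise InputError("hours and days must be positive")
    return hours_per_day * days_per_year


def hourly_cost(monthly_salary: float, hours_per_day: float = 8.0,
                days_per_month: float = 20.0) -> float:
    """Hourly operating cost implied by a professional's monthly salary."""
    if min(monthly_salary, hours_per_day, days_per_month) <= 0:
        raise InputError("salary, hours and days must be positive")
    return monthly_salary / (hours_per_day * days_per_month)
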