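"""Population-ranked siting heuristic used as the comparison baseline.

The heuristic mimics the conventional planning rule "put services where the
people are": candidate sites are ranked by population (descending, ties by
node id), and centers are opened down the ranking, each absorbing capacity
until its own demand could be fully served or the per-intervention budgets
run dry, whichever comes first.  Opening stops when the remaining budgets
cannot fund the minimum viable center (``r_min`` hours).

Flows are then assigned in two passes: every demand node first receives its
minimum-care quota ``phi`` from the nearest open center with spare hours
(prevention hours first — they are cheaper per patient), after which each
open center's residual capacity serves its own municipality's remaining
demand.  The resulting allocation satisfies every model constraint and its
objective values locate the heuristic's *base point* in objective space.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InfeasibleError, InputError
from .optmodel import (N_INTERVENTIONS, ProblemInstance, SolutionAllocation,
                       evaluate_of1, evaluate_of2)

__all__ = ["population_heuristic"]


def population_heuristic(instance: ProblemInstance,
                         populations) -> SolutionAllocation:
    """Greedy population-ranked allocation.

    Parameters
    ----------
    populations : mapping node_id -> population, or a sequence of
        MunicipalityProfile.
    """
    if not isinstance(populations, dict):
        populations = {p.node_id: p.population for p in populations}
    missing = [j for j in instance.site_ids if j not in populations]
    if missing:
        raise InputError(f"populations missing for sites: {missing[:3]}")

    nI, nJ, nK = (len(instance.demand_ids), len(instance.site_ids),
                  N_INTERVENTIONS)
    L = instance.hours_per_patient
    caps = instance.capacity_caps().astype(int)     # per-k fundable hours
    remaining = caps.copy()
    demand_at_site = _site_demand(instance)

    order = sorted(range(nJ),
                   key=lambda j: (-populations[instance.site_ids[j]],
                                  instance.site_ids[j]))
    C = np.zeros((nJ, nK), dtype=int)
    X = np.zeros(nJ, dtype=int)
    r_min = instance.r_min
    for j in order:
        if remaining.sum() < r_min:
            break
        want = np.minimum(remaining,
                          np.ceil(L * demand_at_site[j] - 1e-9).astype(int))
        deficit = max(0, math.ceil(r_min - want.sum()))
        # pad to the minimum viable size from whichever budget has slack
        pad = np.zeros(nK, dtype=int)
        slack = remaining - want
        for k in np.argsort(-slack):
            take = min(deficit, slack[k])
            pad[k] += take
            deficit -= take
        if deficit > 0:
            break
        C[j] = want + pad
        X[j] = 1
        remaining -= C[j]

    if not X.any():
        if instance.phi > 0:
            raise InfeasibleError(
                "budgets cannot fund the minimum viable center while the "
                f"minimum-care level phi={instance.phi} requires service")
        Y = np.zeros((nI, nJ, nK), dtype=int)
        return SolutionAllocation(Y=Y, C=C, X=X, of1=0.0, of2=0.0,
                                  solver_status="heuristic")

    Y = np.zeros((nI, nJ, nK), dtype=int)
    avail = C.astype(float).copy()        # remaining hours per (j, k)
    served = np.zeros((nI, nK), dtype=int)
    dist = instance.distances
    open_js = [j for j in order if X[j]]

    # pass 1: minimum-care quota for every node, nearest open center first
    for i in range(nI):
        need = instance.phi
        for j in sorted(open_js, key=lambda j: dist[i, j]):
            if need <= 0:
                break
            for k in np.argsort(L):      # cheaper hours first
                if need <= 0:
                    break
                can = min(need,
                          int(instance.D[i, k]) - served[i, k],
                          int(avail[j, k] // L[k]) if L[k] > 0 else 0)
                if can > 0:
                    Y[i, j, k] += can
                    served[i, k] += can
                    avail[j, k] -= can * L[k]
                    need -= can
        if need > 0:
            raise InfeasibleError(
                f"heuristic cannot serve the phi={instance.phi} minimum at "
                f"node {instance.demand_ids[i]!r}")

    # pass 2: residual capacity serves the opened city's own demand
    site_to_demand = _site_demand_row(instance)
    for j in open_js:
        i = site_to_demand.get(j)
        if i is None:
            continue
        for k in range(nK):
            can = min(int(instance.D[i, k]) - served[i, k],
                      int(avail[j, k] // L[k]) if L[k] > 0 else 0)
            if can > 0:
                Y[i, j, k] += can
                served[i, k] += can
                avail[j, k] -= can * L[k]

    return SolutionAllocation(
        Y=Y, C=C, X=X,
        of1=evaluate_of1(instance, Y),
        of2=evaluate_of2(instance, Y),
        solver_status="heuristic")


def _site_demand(instance: ProblemInstance) -> np.ndarray:
    """(|J|, 2) demand of each site's own municipality (0 if not a node)."""
    row = _site_demand_row(instance)
    out = np.zeros((len(instance.site_ids), N_INTERVENTIONS), dtype=int)
    for j, i in row.items():
        out[j] = instance.D[i]
    return out


def _site_demand_row(instance: ProblemInstance) -> dict[int, int]:
    pos = {nid: i for i, nid in enumerate(instance.demand_ids)}
    return {j: pos[sid] for j, sid in enumerate(instance.site_ids)
            if sid in pos}
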