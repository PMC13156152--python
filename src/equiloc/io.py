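"""Serialization of solutions and frontiers to JSON/CSV artifacts."""

from __future__ import annotations

import json

import pandas as pd

from .indices import INTERVENTIONS
from .optmodel import ProblemInstance, SolutionAllocation
from .pareto import ParetoFrontier

__all__ = ["solution_to_dict", "write_solution_json", "write_flows_csv",
           "write_frontier_csv", "write_frontier_summary_json"]


def solution_to_dict(instance: ProblemInstance,
                     solution: SolutionAllocation) -> dict:
    return {
        "status": solution.solver_status,
        "gap": solution.gap,
        "of1": solution.of1,
        "of2": solution.of2,
        "open_sites": [instance.site_ids[j] for j in solution.open_sites],
        "X": {instance.site_ids[j]: int(solution.X[j])
              for j in range(len(instance.site_ids))},
        "C": {instance.site_ids[j]: {name: int(solution.C[j, k])
                                     for k, name in enumerate(INTERVENTIONS)}
              for j in solution.open_sites},
    }


def write_solution_json(instance, solution, path) -> None:
    with open(path, "w") as fh:
        json.dump(solution_to_dict(instance, solution), fh, indent=2)


def write_flows_csv(instance: ProblemInstance, solution: SolutionAllocation,
                    path) -> None:
    """Long-format CSV of the nonzero patient flows."""
    rows = []
    for k, name in enumerate(INTERVENTIONS):
        for i, nid in enumerate(instance.demand_ids):
            for j, sid in enumerate(instance.site_ids):
                y = int(solution.Y[i, j, k])
                if y > 0:
                    rows.append({"node_id": nid, "site_id": sid,
                                 "intervention": name, "patients": y})
    pd.DataFrame(rows, columns=["node_id", "site_id", "intervention",
                                "patients"]).to_csv(path, index=False)


def write_frontier_csv(frontier: ParetoFrontier, path) -> None:
    frontier.to_frame().to_csv(path, index=False)


def write_frontier_summary_json(frontier: ParetoFrontier, path) -> None:
    knee = frontier.knee_point
    payload = {
        "ideal": {"of1": frontier.ideal[0], "of2": frontier.ideal[1]},
        "knee": {"index": frontier.knee, "epsilon": knee.epsilon,
                 "of1": knee.of1, "of2": knee.of2},
        "n_points": len(frontier.points),
        "epsilon_grid": frontier.epsilon_grid,
        "skipped": frontier.skipped,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
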