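"""Model construction, objective arithmetic, solving, verification, oracle."""

import math

import numpy as np
import pytest

from conftest import make_instance, random_guarded_instance
from equiloc.errors import InfeasibleError, InputError
from equiloc.optmodel import (assemble_milp, brute_force_solve,
                              build_and_solve, count_variables,
                              default_big_m, evaluate_of1, evaluate_of2,
                              verify_solution)


def two_node_instance(**kw):
    return make_instance(
        R=[[0.9, 0.45], [0.1, 0.05]], sigma=[[0.1, 0.05], [0.8, 0.4]],
        D=[[2, 2], [2, 2]], dist=[[0.0, 10.0], [10.0, 0.0]],
        r_min=2.0, phi=1, **kw)


@pytest.mark.parametrize("shape,expected", [
    ((23, 23, 2), (1127, 23)),
    ((1, 1, 1), (3, 1)),
    ((2, 3, 2), (21, 3)),
])
def test_variable_count_formula(shape, expected):
    assert count_variables(*shape) == expected


@pytest.mark.parametrize("D,expected", [
    ([[3, 1], [2, 4]], 10),
    ([[0, 0], [0, 0]], 0),
    ([[5, 0]], 5),
])
def test_default_big_m_is_total_demand(D, expected):
    D = np.array(D)
    inst = make_instance(R=np.full(D.shape, 0.1), sigma=np.full(D.shape, 0.1),
                         D=D, dist=np.zeros((D.shape[0],) * 2)
                         + 5 * (1 - np.eye(D.shape[0])))
    assert default_big_m(inst) == expected


def test_objective_arithmetic_single_flow():
    # one patient at R=0.5, d=10 km, d_max=20 km, delta=0.7:
    # 0.7*0.5 + 0.3*(-0.5) = 0.20
    inst = make_instance(R=[[0.5, 0.25], [0.0, 0.0]],
                         sigma=[[0.2, 0.1], [0.0, 0.0]],
                         D=[[1, 0], [1, 0]],
                         dist=[[0.0, 10.0], [10.0, 0.0]],
                         delta=0.7, pi_weight=0.5)
    inst.dm.d[0, 1] = 10.0
    inst.dm.d[1, 0] = 20.0  # sets d_max = 20
    Y = np.zeros((2, 2, 2), dtype=int)
    Y[0, 1, 0] = 1
    assert evaluate_of1(inst, Y) == pytest.approx(0.20)
    # OF2 with sigma=0.2, pi=0.5: 0.5*0.2 + 0.5*(-0.5) = -0.15
    assert evaluate_of2(inst, Y) == pytest.approx(-0.15)
    assert evaluate_of1(inst, np.zeros_like(Y)) == 0.0
    inst.delta = 1.0
    assert evaluate_of1(inst, Y) == pytest.approx(0.5)


def test_exact_solver_matches_enumeration_on_tiny_instance():
    inst = two_node_instance()
    exact = build_and_solve(inst, "of1")
    oracle = brute_force_solve(inst, "of1")
    assert exact.of1 == pytest.approx(oracle.of1, abs=1e-9)
    assert verify_solution(inst, exact) == []
    assert verify_solution(inst, oracle) == []


def test_minimum_care_beyond_demand_is_infeasible():
    inst = two_node_instance()
    inst.phi = 5  # node total demand is 4
    with pytest.raises(InfeasibleError, match="phi"):
        build_and_solve(inst, "of1")


def test_zero_budget_closes_everything():
    inst = make_instance(R=[[0.5, 0.25]], sigma=[[0.2, 0.1]], D=[[3, 3]],
                         dist=[[0.0]], budget=(0.0, 0.0), r_min=2.0, phi=0)
    sol = build_and_solve(inst, "of1")
    assert np.all(sol.X == 0) and np.all(sol.Y == 0)
    assert sol.of1 == 0.0 and sol.of2 == 0.0
    inst.phi = 1
    with pytest.raises(InfeasibleError):
        build_and_solve(inst, "of1")


def test_verify_reports_handbuilt_violations():
    inst = two_node_instance()
    sol = build_and_solve(inst, "of1")
    bad = sol.Y.copy()
    bad[0, 0, 0] = 99  # exceeds demand
    from equiloc.optmodel import SolutionAllocation
    report = verify_solution(inst, SolutionAllocation(
        Y=bad, C=sol.C, X=sol.X, of1=0, of2=0, solver_status="optimal"))
    assert any("demand exceeded" in r and "n0" in r for r in report)
    # capacity at a closed site
    C = np.array([[5, 5], [0, 0]])
    X = np.array([0, 0])
    report = verify_solution(inst, SolutionAllocation(
        Y=np.zeros_like(sol.Y), C=C, X=X, of1=0, of2=0,
        solver_status="optimal"))
    assert any("capacity without opening" in r for r in report)


def test_brute_force_guard_refuses_large_instances():
    big = make_instance(R=np.full((4, 2), 0.1), sigma=np.full((4, 2), 0.1),
                        D=np.full((4, 2), 4),
                        dist=5.0 * (1 - np.eye(4)))
    with pytest.raises(InputError, match="guard"):
        brute_force_solve(big)


def test_brute_force_single_site_forced_open_by_phi():
    inst = make_instance(R=[[0.5, 0.25]], sigma=[[0.2, 0.1]], D=[[2, 2]],
                         dist=[[0.0]], r_min=1.0, phi=1)
    sol = brute_force_solve(inst, "of1")
    assert sol.X.tolist() == [1]
    assert sol.Y.sum() >= 1


def test_brute_force_zero_demand_empty_solution():
    inst = make_instance(R=[[0.0, 0.0]], sigma=[[0.0, 0.0]], D=[[0, 0]],
                         dist=[[0.0]], phi=0)
    sol = brute_force_solve(inst, "of1")
    assert sol.of1 == 0.0 and sol.of2 == 0.0 and sol.Y.sum() == 0


def test_epsilon_floor_restricts_the_solver():
    inst = two_node_instance()
    free = build_and_solve(inst, "of1")
    s2 = build_and_solve(inst, "of2")
    floored = build_and_solve(inst, "of1", epsilon_floor=s2.of2)
    assert floored.of2 >= s2.of2 - 1e-6
    assert floored.of1 <= free.of1 + 1e-9


def test_budget_monotonicity_tiny():
    """Doubling budgets can only enlarge the feasible set."""
    inst = random_guarded_instance(11)
    lo1 = build_and_solve(inst, "of1").of1
    lo2 = build_and_solve(inst, "of2").of2
    inst.budget = inst.budget * 2.0
    assert build_and_solve(inst, "of1").of1 >= lo1 - 1e-9
    assert build_and_solve(inst, "of2").of2 >= lo2 - 1e-9


def test_delta_one_monotone_in_risk():
    """With delta=1 the distance term vanishes; raising any R cell cannot
    lower the optimum."""
    inst = random_guarded_instance(5)
    inst.delta = 1.0
    base = build_and_solve(inst, "of1").of1
    inst.R[0, 0] = min(1.0, inst.R[0, 0] + 0.3)
    assert build_and_solve(inst, "of1").of1 >= base - 1e-9


def test_assembled_model_variable_blocks():
    inst = two_node_instance()
    c, constraints, bounds, integrality, lay = assemble_milp(inst, "of1")
    assert lay.n == count_variables(2, 2, 2)[0] == 14
    assert np.all(integrality == 1)
    # the X block is the binary one
    assert np.all(bounds.ub[lay.n_y + lay.n_c:] == 1.0)


def test_solutions_pass_verification_across_random_instances():
    for seed in range(6):
        inst = random_guarded_instance(seed)
        for objective in ("of1", "of2"):
            sol = build_and_solve(inst, objective)
            assert verify_solution(inst, sol) == [], (seed, objective)
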