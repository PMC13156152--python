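"""Frontier generation, non-dominance filtering, knee selection."""

import numpy as np
import pytest

from conftest import make_instance, random_guarded_instance
from equiloc.errors import InputError
from equiloc.optmodel import brute_force_solve, build_and_solve
from equiloc.pareto import (epsilon_sweep, filter_nondominated, ideal_point,
                            select_knee)


def test_filter_drops_dominated_and_duplicates():
    pts = [(1, 5), (3, 3), (2, 2), (5, 1)]
    assert filter_nondominated(pts) == [(1.0, 5.0), (3.0, 3.0), (5.0, 1.0)]
    assert filter_nondominated([(2, 2)]) == [(2.0, 2.0)]
    assert filter_nondominated([(1, 1), (1, 1), (1, 1)]) == [(1.0, 1.0)]


def test_knee_prefers_balanced_point():
    frontier = [(0.0, 10.0), (5.0, 5.0), (10.0, 0.0)]
    assert select_knee(frontier, (10.0, 10.0)) == 1


def test_knee_scale_invariant():
    frontier = [(0.0, 10.0), (5.0, 5.0), (10.0, 0.0)]
    scaled = [(1000.0 * a, b) for a, b in frontier]
    assert select_knee(scaled, (10000.0, 10.0)) == 1


def test_knee_affine_invariance_random_frontier():
    rng = np.random.default_rng(2)
    of1 = np.sort(rng.uniform(0, 100, 7))[::-1]
    of2 = np.sort(rng.uniform(-50, 50, 7))
    frontier = list(zip(of1, of2))
    ideal = (of1.max(), of2.max())
    base = select_knee(frontier, ideal)
    shifted = [(3.0 * a + 7.0, 0.5 * b - 4.0) for a, b in frontier]
    assert select_knee(shifted, (3.0 * ideal[0] + 7.0,
                                 0.5 * ideal[1] - 4.0)) == base


def test_knee_matches_direct_standardized_distance():
    rng = np.random.default_rng(9)
    pts = rng.uniform(-10, 10, size=(6, 2))
    ideal = (pts[:, 0].max() + 1.0, pts[:, 1].max() + 2.0)
    # independent recomputation with explicit loops
    mu, sd = pts.mean(axis=0), pts.std(axis=0)
    dists = []
    for p in pts:
        acc = 0.0
        for c in range(2):
            if sd[c] > 0:
                acc += ((p[c] - mu[c]) / sd[c]
                        - (ideal[c] - mu[c]) / sd[c]) ** 2
        dists.append(acc ** 0.5)
    assert select_knee([tuple(p) for p in pts], ideal) == int(np.argmin(dists))


def test_knee_degenerate_cases():
    assert select_knee([(3.0, 4.0)], (9.0, 9.0)) == 0
    # zero variance in one objective: that coordinate is ignored
    assert select_knee([(5.0, 0.0), (5.0, 10.0)], (5.0, 10.0)) == 1
    with pytest.raises(InputError):
        select_knee([], (0.0, 0.0))


def test_ideal_point_matches_enumeration():
    inst = random_guarded_instance(3)
    of1, of2 = ideal_point(inst)
    assert of1 == pytest.approx(brute_force_solve(inst, "of1").of1, abs=1e-9)
    assert of2 == pytest.approx(brute_force_solve(inst, "of2").of2, abs=1e-9)


def test_zero_demand_ideal_point_is_origin():
    inst = make_instance(R=[[0.0, 0.0]], sigma=[[0.0, 0.0]], D=[[0, 0]],
                         dist=[[0.0]], phi=0)
    assert ideal_point(inst) == (0.0, 0.0)


def test_sweep_matches_constrained_enumeration():
    """Every frontier point's OF1 equals the enumeration optimum under the
    same OF2 floor."""
    inst = random_guarded_instance(4)
    frontier = epsilon_sweep(inst, n_points=5)
    assert len(frontier.points) >= 1
    for p in frontier.points:
        oracle = brute_force_solve(inst, "of1",
                                   epsilon_floor=p.epsilon - 1e-6)
        assert p.of1 == pytest.approx(oracle.of1, abs=1e-9)


def test_sweep_two_points_hits_both_endpoints():
    inst = random_guarded_instance(8)
    s1 = build_and_solve(inst, "of1")
    s2 = build_and_solve(inst, "of2")
    frontier = epsilon_sweep(inst, n_points=2)
    assert frontier.epsilon_grid[0] == pytest.approx(s1.of2)
    assert frontier.epsilon_grid[-1] == pytest.approx(s2.of2)
    assert frontier.points[0].of1 == pytest.approx(s1.of1, abs=1e-9)
    # the last retained point attains (near) the OF2 optimum
    assert max(p.of2 for p in frontier.points) >= s2.of2 - 1e-6


def test_single_feasible_allocation_gives_single_point_frontier():
    # phi forces full service of the only node at the only site
    inst = make_instance(R=[[0.5, 0.25]], sigma=[[0.2, 0.1]], D=[[1, 0]],
                         dist=[[0.0]], r_min=1.0, phi=1)
    frontier = epsilon_sweep(inst, n_points=3)
    assert len(frontier.points) == 1
    assert frontier.knee == 0


def test_frontier_invariants_on_small_network(small_network):
    _, inst = small_network
    frontier = epsilon_sweep(inst, n_points=6)
    pairs = [(p.of1, p.of2) for p in frontier.points]
    assert filter_nondominated(pairs) == pairs  # mutually non-dominated
    for a, b in zip(frontier.points, frontier.points[1:]):
        assert a.epsilon <= b.epsilon
        assert b.of1 <= a.of1 + 1e-6 + 1e-4 * abs(a.of1)
    of1_star, of2_star = frontier.ideal
    for p in frontier.points:
        assert of1_star >= p.of1 - 1e-6 - 1e-4 * abs(p.of1)
        assert of2_star >= p.of2 - 1e-6 - 1e-4 * abs(p.of2)
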