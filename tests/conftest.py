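"""Shared fixtures: tiny hand-built instances, random guarded instances for
the enumeration oracle, and a session-scoped 23-node network with its
20-point Pareto frontier (expensive; computed once)."""

from __future__ import annotations

import numpy as np
import pytest

from equiloc.geo import DistanceMatrix
from equiloc.indices import MunicipalityProfile
from equiloc.optmodel import ProblemInstance
from equiloc.pareto import epsilon_sweep
from equiloc.synth import GeneratorConfig, generate_instance


def make_profile(i=0, **kw) -> MunicipalityProfile:
    """One municipality with plausible defaults, overridable per field."""
    base = dict(node_id=f"m{i}", name=f"town{i}", latitude=10.5,
                longitude=-74.9, population=1000, demand_prevention=10,
                demand_mitigation=20, consumers=20, posts_negative=5,
                posts_neutral=3, posts_positive=2, crime_incidents=4,
                mpi=0.3, rurality=0.4)
    base.update(kw)
    return MunicipalityProfile(**base)


def make_instance(R, sigma, D, dist, *, budget=(1e6, 1e6),
                  hourly_cost=(10.0, 10.0), hours_per_patient=(0.5, 1.0),
                  r_min=2.0, phi=0, delta=0.7, pi_weight=0.7,
                  big_m=None, phi_k=None) -> ProblemInstance:
    """Hand-built square instance; every node is demand node and site."""
    D = np.atleast_2d(np.asarray(D))
    n = D.shape[0]
    ids = [f"n{i}" for i in range(n)]
    dist = np.asarray(dist, dtype=float)
    return ProblemInstance(
        demand_ids=ids, site_ids=list(ids),
        R=np.asarray(R, dtype=float), sigma=np.asarray(sigma, dtype=float),
        D=D, dm=DistanceMatrix(ids, dist),
        budget=np.asarray(budget, dtype=float),
        hourly_cost=np.asarray(hourly_cost, dtype=float),
        hours_per_patient=np.asarray(hours_per_patient, dtype=float),
        r_min=r_min, phi=phi, delta=delta, pi_weight=pi_weight,
        big_m=big_m, phi_k=phi_k)


def symmetric_distances(rng, n, scale=50.0):
    d = rng.uniform(1.0, scale, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def random_guarded_instance(seed: int) -> ProblemInstance:
    """Random instance inside the enumeration-oracle guard, feasible by
    construction (budgets cover full service plus the minimum-hours floor)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 4))            # 2-3 nodes, square network
    D = rng.integers(0, 3, size=(n, 2))
    D[D.sum(axis=1) == 0, 0] = 1           # every node has some demand
    while D.sum() > 8:
        i, k = rng.integers(0, n), rng.integers(0, 2)
        if D[i, k] > 0 and D[i].sum() > 1:
            D[i, k] -= 1
    R1 = rng.uniform(0.0, 1.0, n)
    S1 = rng.uniform(0.0, 1.0, n)
    R = np.column_stack([R1, R1 / 2.0])
    sigma = np.column_stack([S1, S1 / 2.0])
    L = np.array([0.5, 1.0])
    F = np.array([2.0, 3.0])
    r_min = float(rng.integers(1, 4))
    # full-service budget plus slack for the per-site minimum hours
    budget = F * (L * D.sum(axis=0) + r_min * n)
    phi = int(rng.integers(0, 2)) if D.sum(axis=1).min() >= 1 else 0
    return make_instance(R, sigma, D, symmetric_distances(rng, n),
                         budget=tuple(budget), hourly_cost=tuple(F),
                         hours_per_patient=tuple(L), r_min=r_min, phi=phi,
                         delta=float(rng.uniform(0.2, 0.9)),
                         pi_weight=float(rng.uniform(0.2, 0.9)))


@pytest.fixture(scope="session")
def network23():
    """Default 23-municipality synthetic network (the study-scale fixture)."""
    return generate_instance(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def frontier23(network23):
    """20-point epsilon sweep on the 23-node network (shared: expensive)."""
    _, instance = network23
    return epsilon_sweep(instance, n_points=20)


@pytest.fixture()
def small_network():
    """Fast 6-node network for pipeline-level tests."""
    return generate_instance(GeneratorConfig(seed=7, n_nodes=6))
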