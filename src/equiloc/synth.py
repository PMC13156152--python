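"""Reproducible synthetic municipality networks.

The generator emulates the statistical structure of a Caribbean-coast
department: ~23 municipalities, one dominant capital holding the majority of
the population and an even larger majority of the social-media posts,
heavy-tailed town sizes, and poverty/rurality that fall with population.
Per-intervention demand follows the two-at-mitigation-per-one-at-prevention
structure of the risk model, and budgets are set as a fraction of the
full-service cost so that capacity genuinely binds.

``atlantico_fixture`` builds a named 23-municipality instance carrying every
scalar the study area publishes (budgets, salaries, service times, minimum
hours, objective weights, the per-town post counts); quantities that are not
public — demands, poverty, rurality, coordinates — are synthetic stand-ins
drawn from a fixed seed and must not be read as the real department.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import analytics
from .errors import InputError
from .geo import haversine_matrix
from .indices import MunicipalityProfile, compute_index_table
from .optmodel import ProblemInstance

__all__ = ["GeneratorConfig", "generate_instance", "atlantico_fixture",
           "instance_from_profiles"]

log = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic network; defaults are the study conditions."""

    seed: int
    n_nodes: int = 23
    lat_range: tuple[float, float] = (10.2, 11.1)
    lon_range: tuple[float, float] = (-75.3, -74.7)
    #: log-normal town sizes; the dominant capital is forced to this share
    pop_median: float = 20000.0
    pop_sigma: float = 1.0
    pop_min: int = 5000
    dominant_share: float = 0.6
    #: fraction of the population estimated to consume the target substance
    consumption_rate: float = 0.02
    #: posts per capita; the capital posts at a multiple of everyone else
    posts_rate: float = 0.004
    dominant_posts_multiplier: float = 5.0
    sentiment_split: tuple[float, float, float] = (0.5, 0.3, 0.2)
    incidents_rate: float = 0.01
    mpi_range: tuple[float, float] = (0.1, 0.8)
    rurality_range: tuple[float, float] = (0.05, 0.9)
    #: per-intervention budget as a fraction of the full-service cost
    budget_fraction: float = 0.3
    phi: int = 5
    delta: float = 0.7
    pi_weight: float = 0.7
    hours_per_patient: tuple[float, float] = (0.05, 1.0)
    r_min: float = 2080.0
    monthly_salaries: tuple[float, float] = (1.8e6, 6.1e6)
    mip_gap: float = 1e-4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("a seed is mandatory; no implicit randomness")
        if abs(sum(self.sentiment_split) - 1.0) > 1e-9:
            raise InputError("sentiment split must sum to 1")
        if not 0 < self.dominant_share < 1:
            raise InputError("dominant_share must lie in (0, 1)")
        if self.n_nodes < 1:
            raise InputError("n_nodes must be positive")


def _rank_correlated(rng, values, lo, hi, noise=0.08):
    """Sample in [lo, hi], decreasing in the rank of ``values`` plus noise."""
    n = len(values)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(values)] = np.arange(n)          # 0 = smallest value
    base = hi - (hi - lo) * ranks / max(n - 1, 1)     # small -> hi
    out = base + rng.normal(0.0, noise * (hi - lo), n)
    return np.clip(out, lo, hi)


def generate_instance(config: GeneratorConfig):
    """Generate ``(profiles, ProblemInstance)`` deterministically from a seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes

    lat = rng.uniform(*config.lat_range, n)
    lon = rng.uniform(*config.lon_range, n)

    pops = np.maximum(
        rng.lognormal(np.log(config.pop_median), config.pop_sigma, n),
        config.pop_min).astype(int)
    if n > 1:
        share = config.dominant_share
        pops[0] = int(round(share / (1.0 - share) * pops[1:].sum()))

    consumers = rng.binomial(pops, config.consumption_rate)
    consumers = np.maximum(consumers, 1)

    post_rate = np.full(n, config.posts_rate)
    post_rate[0] *= config.dominant_posts_multiplier
    posts_total = rng.poisson(pops * post_rate)
    posts = np.array([rng.multinomial(t, config.sentiment_split)
                      for t in posts_total])

    incidents = rng.poisson(pops * config.incidents_rate)
    mpi = _rank_correlated(rng, pops, *config.mpi_range)
    rurality = _rank_correlated(rng, pops, *config.rurality_range)

    demand_mit = consumers.copy()
    demand_prev = np.maximum(consumers // 2, 1)

    profiles = [MunicipalityProfile(
        node_id=f"m{i:02d}", name=f"town-{i:02d}",
        latitude=float(lat[i]), longitude=float(lon[i]),
        population=int(pops[i]),
        demand_prevention=int(demand_prev[i]),
        demand_mitigation=int(demand_mit[i]),
        consumers=int(consumers[i]),
        posts_negative=int(posts[i, 0]), posts_neutral=int(posts[i, 1]),
        posts_positive=int(posts[i, 2]),
        crime_incidents=int(incidents[i]),
        mpi=float(mpi[i]), rurality=float(rurality[i]),
    ) for i in range(n)]

    hourly = tuple(analytics.hourly_cost(s) for s in config.monthly_salaries)
    D = np.column_stack([demand_prev, demand_mit])
    budget = fraction_budget(D, config)

    instance = instance_from_profiles(
        profiles, budget=budget, hourly_cost=hourly,
        hours_per_patient=config.hours_per_patient, r_min=config.r_min,
        phi=config.phi, delta=config.delta, pi_weight=config.pi_weight,
        mip_gap=config.mip_gap)
    return profiles, instance


def fraction_budget(D: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Per-intervention budget: a fraction of the full-service cost, bumped
    (doubled, logged) until it passes the feasibility precheck — fund the
    minimum-care load and at least one minimum-size center."""
    L = np.asarray(config.hours_per_patient)
    F = np.array([analytics.hourly_cost(s) for s in config.monthly_salaries])
    budget = config.budget_fraction * F * L * D.sum(axis=0)
    for _ in range(40):
        caps = np.floor(budget / F)
        servable = float(np.sum(caps / L))
        if caps.sum() >= config.r_min and servable >= config.phi * D.shape[0]:
            break
        log.warning("seed %d: budget %s infeasible for phi=%d; doubling",
                    config.seed, budget, config.phi)
        budget = budget * 2.0
    return budget


def instance_from_profiles(profiles, *, budget, hourly_cost,
                           hours_per_patient, r_min, phi, delta, pi_weight,
                           mip_gap=1e-4, dm=None) -> ProblemInstance:
    """Assemble a ProblemInstance from profiles (every node is a candidate)."""
    table = compute_index_table(profiles)
    R = table[["R1", "R2"]].to_numpy()
    sigma = table[["sigma1", "sigma2"]].to_numpy()
    D = np.array([[p.demand_prevention, p.demand_mitigation]
                  for p in profiles])
    ids = [p.node_id for p in profiles]
    return ProblemInstance(
        demand_ids=ids, site_ids=list(ids), R=R, sigma=sigma, D=D,
        dm=dm if dm is not None else haversine_matrix(profiles),
        budget=np.asarray(budget, dtype=float),
        hourly_cost=np.asarray(hourly_cost, dtype=float),
        hours_per_patient=np.asarray(hours_per_patient, dtype=float),
        r_min=r_min, phi=phi, delta=delta, pi_weight=pi_weight,
        mip_gap=mip_gap)


# per-town post counts as published; multi-town rows are split evenly with
# the remainder to the first-listed town
_POST_ROWS = [
    (("Barranquilla",), 2741),
    (("Baranoa",), 18),
    (("Campo de la Cruz", "Candelaria", "Galapa"), 11),
    (("Juan de Acosta",), 11),
    (("Luruaco", "Malambo"), 24),
    (("Manatí",), 1),
    (("Palmar de Varela",), 1),
    (("Piojó", "Polonuevo"), 5),
    (("Ponedera",), 1),
    (("Puerto Colombia",), 108),
    (("Repelón", "Sabanagrande"), 8),
    (("Sabanalarga",), 24),
    (("Santa Lucía", "Santo Tomás"), 1),
    (("Soledad",), 124),
    (("Suan", "Tubará"), 5),
    (("Usiacurí",), 2),
]

PREVENTION_BUDGET_COP = 654_000_000.0
MITIGATION_BUDGET_COP = 3_000_000_000.0
PSYCHOLOGIST_SALARY_COP = 1_800_000.0   # prevention professional
PSYCHIATRIST_SALARY_COP = 6_100_000.0   # mitigation professional

_FIXTURE_SEED = 1906


def _split_posts() -> dict[str, int]:
    out = {}
    for towns, total in _POST_ROWS:
        m = len(towns)
        base, rem = divmod(total, m)
        for t, town in enumerate(towns):
            out[town] = base + (1 if t < rem else 0)
    return out


def atlantico_fixture(phi: int = 100, seed: int = _FIXTURE_SEED):
    """Named 23-town instance with the published scalars; the rest synthetic.

    Budgets (654M COP prevention / 3,000M COP mitigation), professional
    salaries, service times (0.05 h and 1 h per patient), the 2080-hour
    minimum, the 0.7 objective weights and the per-town post distribution
    are the published figures.  Populations, demands, poverty, rurality,
    incidents and coordinates are synthetic stand-ins from a fixed seed:
    demand is scaled so the published budgets fund roughly a third of the
    service hours it requires, making the budget genuinely bind.
    """
    posts_by_town = _split_posts()
    names = list(posts_by_town)
    n = len(names)
    rng = np.random.default_rng(seed)

    lat = rng.uniform(10.25, 11.05, n)
    lon = rng.uniform(-75.25, -74.75, n)
    pops = np.maximum(rng.lognormal(np.log(9000.0), 0.9, n), 3000).astype(int)
    pops[0] = int(round(0.6 / 0.4 * pops[1:].sum()))  # the capital dominates

    hourly = np.array([analytics.hourly_cost(PSYCHOLOGIST_SALARY_COP),
                       analytics.hourly_cost(PSYCHIATRIST_SALARY_COP)])
    budget = np.array([PREVENTION_BUDGET_COP, MITIGATION_BUDGET_COP])
    L = np.array([0.05, 1.0])
    # budgets should fund about a third of total demand hours
    target_mit = int(3 * (budget[1] / hourly[1]) / L[1])
    demand_mit = np.maximum(
        np.rint(target_mit * pops / pops.sum()).astype(int), 2 * phi)
    demand_prev = np.maximum(demand_mit // 2, phi)

    # published counts are town totals; split deterministically into a
    # majority-negative sentiment mix so each town total stays exact
    posts_total = np.array([posts_by_town[nm] for nm in names])
    posts_neg = (posts_total + 1) // 2
    posts_neu = (posts_total - posts_neg + 1) // 2
    posts_pos = posts_total - posts_neg - posts_neu
    incidents = rng.poisson(pops * 0.01)
    mpi = _rank_correlated(rng, pops, 0.1, 0.8)
    rurality = _rank_correlated(rng, pops, 0.05, 0.9)

    profiles = [MunicipalityProfile(
        node_id=nm, name=nm,
        latitude=float(lat[i]), longitude=float(lon[i]),
        population=int(pops[i]),
        demand_prevention=int(demand_prev[i]),
        demand_mitigation=int(demand_mit[i]),
        consumers=int(demand_mit[i]),
        posts_negative=int(posts_neg[i]),
        posts_neutral=int(posts_neu[i]),
        posts_positive=int(posts_pos[i]),
        crime_incidents=int(incidents[i]),
        mpi=float(mpi[i]), rurality=float(rurality[i]),
    ) for i, nm in enumerate(names)]

    instance = instance_from_profiles(
        profiles, budget=budget, hourly_cost=hourly,
        hours_per_patient=L, r_min=2080.0, phi=phi,
        delta=0.7, pi_weight=0.7)
    return profiles, instance
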