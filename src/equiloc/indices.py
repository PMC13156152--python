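"""Composite risk and equity indices for municipality networks.

Each municipality (node) carries raw observables: an estimated count of
psychoactive-substance consumers, sentiment-labeled social-media post counts,
crime incidents, a multidimensional poverty index (MPI) and a rurality
proportion (RP).  From these the module derives the per-node shares

* ``alpha``  — share of estimated consumers held by the node,
* ``psi``    — share of negative posts held by the node,
* ``gamma``  — share of crime incidents held by the node,

the composite *risk* index ``R1 = (alpha + psi + gamma) / 3`` with its
mitigation counterpart ``R2 = R1 / 2`` (one person at prevention risk for
every two at mitigation risk), and the *equity* index ``sigma1 = RP * MPI``
with ``sigma2 = sigma1 / 2``.  The multiplicative equity form follows the
composite-indicator practice of the multidimensional poverty literature: a
low value on one deprivation axis cannot be compensated by the other.

Nodes with no posts anywhere receive ``psi = 0`` (absence of social-media
signal is treated as zero contribution, not missing data); the same all-zero
convention applies to consumers and incidents so that degenerate synthetic
inputs remain runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "MunicipalityProfile",
    "compute_alpha",
    "compute_psi",
    "compute_gamma",
    "compute_risk",
    "compute_equity",
    "compute_index_table",
    "read_profiles_csv",
    "write_profiles_csv",
    "write_index_csv",
]

#: prevention is intervention k=1 (array index 0), mitigation k=2 (index 1)
INTERVENTIONS = ("prevention", "mitigation")


@dataclass(frozen=True)
class MunicipalityProfile:
    """Raw per-node attributes of one municipality."""

    node_id: str
    name: str
    latitude: float
    longitude: float
    population: int
    demand_prevention: int
    demand_mitigation: int
    consumers: int
    posts_negative: int
    posts_neutral: int
    posts_positive: int
    crime_incidents: int
    mpi: float
    rurality: float

    def __post_init__(self) -> None:
        for f in ("population", "demand_prevention", "demand_mitigation",
                  "consumers", "posts_negative", "posts_neutral",
                  "posts_positive", "crime_incidents"):
            v = getattr(self, f)
            if v < 0 or int(v) != v:
                raise InputError(f"{f} must be a nonnegative integer, got {v!r}")
        for f in ("mpi", "rurality"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{f} must lie in [0, 1], got {v!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise InputError(f"latitude out of range: {self.latitude!r}")
        if not -180.0 <= self.longitude <= 180.0:
            raise InputError(f"longitude out of range: {self.longitude!r}")


def _share(counts: np.ndarray) -> np.ndarray:
    """Normalize counts to shares; an all-zero total yields all-zero shares."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InputError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    return counts / total


def _require_profiles(profiles) -> list:
    profiles = list(profiles)
    if not profiles:
        raise InputError("at least one municipality profile is required")
    return profiles


def compute_alpha(profiles) -> np.ndarray:
    """Per-node share of estimated substance consumers."""
    profiles = _require_profiles(profiles)
    return _share([p.consumers for p in profiles])


def compute_psi(profiles) -> np.ndarray:
    """Per-node share of negative posts; nodes without posts contribute 0."""
    profiles = _require_profiles(profiles)
    return _share([p.posts_negative for p in profiles])


def compute_gamma(profiles) -> np.ndarray:
    """Per-node share of crime incidents (homicides, thefts, threats, ...)."""
    profiles = _require_profiles(profiles)
    return _share([p.crime_incidents for p in profiles])


def compute_risk(alpha, psi, gamma) -> tuple[np.ndarray, np.ndarray]:
    """Composite risk per node: R1 = (alpha+psi+gamma)/3 and R2 = R1/2.

    Returns
    -------
    (R1, R2) : prevention and mitigation risk vectors, each in [0, 1].
    """
    alpha, psi, gamma = (np.asarray(v, dtype=float) for v in (alpha, psi, gamma))
    if not (alpha.shape == psi.shape == gamma.shape):
        raise InputError("alpha, psi, gamma must have identical shapes")
    for name, v in (("alpha", alpha), ("psi", psi), ("gamma", gamma)):
        if np.any((v < 0) | (v > 1)):
            raise InputError(f"{name} entries must lie in [0, 1]")
    r1 = (alpha + psi + gamma) / 3.0
    return r1, r1 / 2.0


def compute_equity(mpi, rurality) -> tuple[np.ndarray, np.ndarray]:
    """Equity index per node: sigma1 = RP * MPI and sigma2 = sigma1/2."""
    mpi = np.asarray(mpi, dtype=float)
    rurality = np.asarray(rurality, dtype=float)
    if mpi.shape != rurality.shape:
        raise InputError("mpi and rurality must have identical shapes")
    if np.any((mpi < 0) | (mpi > 1)) or np.any((rurality < 0) | (rurality > 1)):
        raise InputError("mpi and rurality entries must lie in [0, 1]")
    s1 = rurality * mpi
    return s1, s1 / 2.0


def compute_index_table(profiles) -> pd.DataFrame:
    """Compute the full per-node index table from raw profiles.

    The table is intended to be computed once and frozen before optimization;
    editing profiles afterwards requires an explicit recomputation.

    Returns a DataFrame indexed 0..n-1 with columns
    ``node_id, alpha, psi, gamma, R1, R2, sigma1, sigma2``.
    """
    profiles = _require_profiles(profiles)
    alpha = compute_alpha(profiles)
    psi = compute_psi(profiles)
    gamma = compute_gamma(profiles)
    r1, r2 = compute_risk(alpha, psi, gamma)
    s1, s2 = compute_equity([p.mpi for p in profiles],
                            [p.rurality for p in profiles])
    return pd.DataFrame({
        "node_id": [p.node_id for p in profiles],
        "alpha": alpha, "psi": psi, "gamma": gamma,
        "R1": r1, "R2": r2, "sigma1": s1, "sigma2": s2,
    })


_PROFILE_COLUMNS = [f.name for f in fields(MunicipalityProfile)]


def read_profiles_csv(path) -> list[MunicipalityProfile]:
    """Load municipality profiles from a CSV with the canonical column names."""
    df = pd.read_csv(path)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"profile CSV {path} is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _PROFILE_COLUMNS}
        for f in fields(MunicipalityProfile):
            if f.type in ("int", int):
                kwargs[f.name] = int(kwargs[f.name])
            elif f.type in ("float", float):
                kwargs[f.name] = float(kwargs[f.name])
            else:
                kwargs[f.name] = str(kwargs[f.name])
        out.append(MunicipalityProfile(**kwargs))
    return out


def write_profiles_csv(profiles, path) -> None:
    pd.DataFrame([vars(p) if not hasattr(p, "__dataclass_fields__")
                  else {f: getattr(p, f) for f in _PROFILE_COLUMNS}
                  for p in profiles])[_PROFILE_COLUMNS].to_csv(path, index=False)


def write_index_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
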