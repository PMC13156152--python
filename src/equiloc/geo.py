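"""Inter-node distance matrices and radius masks.

Distances enter the objective functions only through the normalized form
``-d_ij / d_max`` with ``d_max`` the single global maximum of the matrix, so
the container tracks that maximum alongside the raw kilometre entries.

Real deployments feed a driving-distance matrix from a routing service via
CSV; the built-in fallback is the haversine great-circle distance on node
coordinates (Earth radius 6371.0 km).  No road-network routing is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = ["DistanceMatrix", "haversine_matrix", "load_distance_csv",
           "within_radius"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Kilometre distances between demand nodes (rows) and sites (columns)."""

    node_ids: list[str]
    d: np.ndarray  # (n, n) km, nonnegative, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.node_ids)
        if self.d.shape != (n, n):
            raise InputError(
                f"distance matrix shape {self.d.shape} does not match "
                f"{n} node ids")
        if np.any(self.d < 0):
            raise InputError("distances must be nonnegative")
        if np.any(np.diag(self.d) != 0):
            raise InputError("self-distances must be zero")

    @property
    def d_max(self) -> float:
        """Global maximum distance, the normalizer of both objectives."""
        return float(self.d.max()) if self.d.size else 0.0

    def normalized(self) -> np.ndarray:
        """``d / d_max`` in [0, 1]; all zeros for a degenerate single node."""
        dmax = self.d_max
        if dmax == 0.0:
            return np.zeros_like(self.d)
        return self.d / dmax


def haversine_matrix(profiles) -> DistanceMatrix:
    """Great-circle distance matrix (km) from node coordinates."""
    profiles = list(profiles)
    if not profiles:
        raise InputError("at least one profile is required")
    lat = np.radians([p.latitude for p in profiles])
    lon = np.radians([p.longitude for p in profiles])
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise InputError("coordinates must be finite")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([p.node_id for p in profiles], d)


def load_distance_csv(path) -> DistanceMatrix:
    """Load a distance matrix from CSV, square or long format.

    Square format: header row of node ids, first column of node ids, km cells.
    Long format: columns ``origin,destination,km``; every ordered pair over
    the node set must be present.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] == ["origin", "destination", "km"]:
        return _from_long(df, path)
    return _from_square(df, path)


def _from_long(df: pd.DataFrame, path) -> DistanceMatrix:
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    ids = sorted(set(df["origin"].astype(str)) | set(df["destination"].astype(str)))
    pos = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    d = np.full((n, n), np.nan)
    for _, row in df.iterrows():
        o, t, km = str(row["origin"]), str(row["destination"]), float(row["km"])
        if km < 0:
            raise FormatError(f"{path}: negative distance at ({o}, {t}): {km}")
        d[pos[o], pos[t]] = km
    missing = np.argwhere(np.isnan(d))
    if len(missing):
        i, j = missing[0]
        raise FormatError(f"{path}: missing distance for pair ({ids[i]}, {ids[j]})")
    return DistanceMatrix(ids, d)


def _from_square(df: pd.DataFrame, path) -> DistanceMatrix:
    first = df.columns[0]
    ids = [str(v) for v in df[first]]
    col_ids = [str(c) for c in df.columns[1:]]
    if len(col_ids) != len(ids):
        raise FormatError(
            f"{path}: square matrix has {len(ids)} rows but {len(col_ids)} "
            "distance columns")
    unknown = [c for c in col_ids if c not in set(ids)]
    if unknown:
        raise FormatError(f"{path}: unknown node id in header: {unknown[0]}")
    body = df[df.columns[1:]]
    try:
        d = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric distance cell ({exc})") from exc
    nan = np.argwhere(np.isnan(d))
    if len(nan):
        i, j = nan[0]
        raise FormatError(
            f"{path}: missing distance for pair ({ids[i]}, {col_ids[j]})")
    neg = np.argwhere(d < 0)
    if len(neg):
        i, j = neg[0]
        raise FormatError(
            f"{path}: negative distance at ({ids[i]}, {col_ids[j]}): {d[i, j]}")
    # reorder columns to row order
    order = [col_ids.index(i) for i in ids]
    return DistanceMatrix(ids, d[:, order])


def write_distance_csv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.d, index=dm.node_ids, columns=dm.node_ids).to_csv(
        path, index_label="node_id")


def within_radius(dm: DistanceMatrix, radius_km: float) -> np.ndarray:
    """Boolean mask: entry (i, j) true iff d_ij <= radius_km (inclusive)."""
    if radius_km <= 0:
        raise InputError(f"radius must be positive, got {radius_km}")
    return dm.d <= radius_km
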