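"""Design-matrix construction from panel history, geography, time and SVI.

Every feature for a (tract, target-year) row is computed from observed
counts in years strictly before the target year, so rolling one-step-ahead
forecasts never leak the year being predicted.  SVI percentiles are
exogenous published covariates and are taken at the target year itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel import SVI_COLUMNS, TractYearPanel

__all__ = [
    "FeatureMatrix",
    "build_history_features",
    "build_spatial_lag_features",
    "assemble_design_matrix",
    "nearest_neighbor_indices",
    "Standardizer",
]

logger = logging.getLogger(__name__)

_EARTH_RADIUS_KM = 6371.0


@dataclass
class FeatureMatrix:
    """Aligned rows of (tract index, target year), features and targets."""

    rows: list[tuple[int, int]]
    X: np.ndarray
    columns: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.rows), len(self.columns)):
            raise ValueError("X shape inconsistent with rows/columns")
        if len(self.y) != len(self.rows):
            raise ValueError("y length inconsistent with rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")


def _target_rows(panel: TractYearPanel, target_years: Sequence[int]) -> list[tuple[int, int]]:
    return [(s, int(t)) for t in target_years for s in range(panel.S)]


def build_history_features(
    panel: TractYearPanel,
    target_years: Sequence[int],
    W: int,
    zero_pad: bool = False,
) -> FeatureMatrix:
    """Lagged-count block: columns lag_1 ... lag_W, lag_j = y[s, t - j].

    Requires W years of history before every target year unless
    ``zero_pad`` substitutes zeros for lags preceding the panel start.
    """
    if W <= 0:
        raise ValueError("W must be a positive integer")
    for t in target_years:
        if not zero_pad and panel.time_index(t) < W:
            raise ValueError(
                f"target year {t} has only {panel.time_index(t)} prior panel years "
                f"(need W={W}; pass zero_pad=True to pad)"
            )
    rows = _target_rows(panel, target_years)
    X = np.zeros((len(rows), W))
    y = np.zeros(len(rows))
    for i, (s, t) in enumerate(rows):
        j_t = panel.year_index(t)
        for j in range(1, W + 1):
            X[i, j - 1] = panel.counts[s, j_t - j] if j_t - j >= 0 else 0.0
        y[i] = panel.counts[s, j_t]
    return FeatureMatrix(rows=rows, X=X, columns=[f"lag_{j}" for j in range(1, W + 1)], y=y)


def _haversine_matrix(centroids: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between centroid rows."""
    lat = np.radians(centroids[:, 0])
    lon = np.radians(centroids[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def nearest_neighbor_indices(panel: TractYearPanel, n_neighbors: int) -> np.ndarray:
    """(S, n_neighbors) indices of each tract's nearest tracts (self excluded).

    Great-circle distance on centroids; ties (e.g. duplicate centroids) are
    broken deterministically by tract order via a stable sort, with a
    logged warning when duplicates exist.
    """
    S = panel.S
    if not (1 <= n_neighbors < S):
        raise ValueError(f"n_neighbors must be in [1, S-1], got {n_neighbors} for S={S}")
    d = _haversine_matrix(panel.centroids)
    np.fill_diagonal(d, np.inf)
    if np.any(d == 0):
        logger.warning("duplicate centroids detected; neighbor ties broken by tract order")
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :n_neighbors]


def build_spatial_lag_features(
    panel: TractYearPanel,
    target_years: Sequence[int],
    n_neighbors: int = 5,
) -> FeatureMatrix:
    """Spatial-lag block: mean prior-year count over the k nearest tracts.

    For row (s, t) the single column ``splag_k{n}`` is the mean of
    y[s', t-1] over the ``n_neighbors`` tracts nearest to s.
    """
    for t in target_years:
        if panel.time_index(t) < 1:
            raise ValueError(f"target year {t} has no prior year for the spatial lag")
    nbrs = nearest_neighbor_indices(panel, n_neighbors)
    rows = _target_rows(panel, target_years)
    X = np.zeros((len(rows), 1))
    y = np.zeros(len(rows))
    for i, (s, t) in enumerate(rows):
        j_t = panel.year_index(t)
        X[i, 0] = panel.counts[nbrs[s], j_t - 1].mean()
        y[i] = panel.counts[s, j_t]
    return FeatureMatrix(rows=rows, X=X, columns=[f"splag_k{n_neighbors}"], y=y)


class Standardizer:
    """Column-wise shift/scale fitted on training rows only.

    SVI columns (already percentiles in [0, 1]) are passed through; every
    other column is centred and scaled by its training mean and SD.  The
    fitted statistics are reused verbatim at validation/prediction time.
    """

    def __init__(self) -> None:
        self.columns: list[str] | None = None
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray, columns: Sequence[str]) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.columns = list(columns)
        skip = np.array([c in SVI_COLUMNS for c in columns])
        self.mean_ = np.where(skip, 0.0, X.mean(axis=0))
        sd = X.std(axis=0)
        self.scale_ = np.where(skip | (sd == 0), 1.0, sd)
        return self

    def transform(self, X: np.ndarray, columns: Sequence[str]) -> np.ndarray:
        if self.columns is None:
            raise RuntimeError("Standardizer not fitted")
        if list(columns) != self.columns:
            raise ValueError("column mismatch between fit and transform")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def assemble_design_matrix(
    blocks: Sequence[FeatureMatrix],
    panel: TractYearPanel | None = None,
    include_svi: bool = False,
    include_geo_time: bool = False,
    standardize: bool = False,
    standardizer: Standardizer | None = None,
) -> tuple[FeatureMatrix, Standardizer | None]:
    """Concatenate feature blocks plus optional geo/time and SVI columns.

    All blocks must share an identical row set.  With ``standardize`` a new
    :class:`Standardizer` is fitted on the assembled rows (treat these as
    training rows); passing an existing ``standardizer`` instead applies
    previously fitted statistics, so prediction-time rows never contribute
    to the shift/scale.
    """
    if not blocks:
        raise ValueError("need at least one feature block")
    rows = blocks[0].rows
    for b in blocks[1:]:
        if b.rows != rows:
            raise ValueError("feature blocks have mismatched row sets")
    parts = [b.X for b in blocks]
    columns = [c for b in blocks for c in b.columns]

    if include_geo_time:
        if panel is None:
            raise ValueError("panel required for geo/time columns")
        geo = np.array(
            [[panel.centroids[s, 0], panel.centroids[s, 1], panel.time_index(t)]
             for s, t in rows]
        )
        parts.append(geo)
        columns += ["lat", "lon", "time_index"]
    if include_svi:
        if panel is None or panel.svi is None:
            raise ValueError("panel with SVI covariates required for include_svi")
        svi = np.array([panel.svi[s, panel.year_index(t), :] for s, t in rows])
        parts.append(svi)
        columns += list(SVI_COLUMNS)

    X = np.hstack(parts)
    if standardizer is not None:
        X = standardizer.transform(X, columns)
    elif standardize:
        standardizer = Standardizer().fit(X, columns)
        X = standardizer.transform(X, columns)
    return FeatureMatrix(rows=list(rows), X=X, columns=columns, y=blocks[0].y.copy()), standardizer
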