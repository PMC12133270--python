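"""Tract-year count panels: the universal data object of the package.

A :class:`TractYearPanel` holds observed annual fatal-overdose counts
``y[s, t]`` for ``S`` census tracts over ``T`` consecutive calendar years,
together with tract-centroid coordinates and (optionally) a 5-dimensional
Social Vulnerability Index percentile covariate per tract-year.  Panels are
exchanged on disk as long-format CSV, one row per tract-year.

Counts are dense: a tract-year with no events is an explicit zero, never a
missing row (an opt-in ``fill_missing_zero`` flag exists for convenience,
but silent zero-filling is off by default because it hides data errors).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TractYearPanel",
    "SplitSpec",
    "EvalConfig",
    "SVI_COLUMNS",
    "read_panel_csv",
    "write_panel_csv",
    "load_config",
]

#: Canonical SVI covariate column names: four domains plus the composite,
#: each a statewide percentile rank in [0, 1].
SVI_COLUMNS = (
    "svi_socioeconomic",
    "svi_age",
    "svi_minority",
    "svi_housing",
    "svi_overall",
)

_BASE_COLUMNS = ("tract_id", "year", "deaths", "lat", "lon")


@dataclass
class TractYearPanel:
    """Observed counts plus geometry and covariates for S tracts x T years.

    Parameters
    ----------
    tract_ids
        S unique string identifiers (GEOID-style strings fit naturally but
        any opaque string works).  Stored sorted; all index-based access in
        the package uses this fixed order.
    years
        T strictly consecutive integer calendar years.
    counts
        (S, T) array of non-negative integer fatal-overdose counts.
    centroids
        (S, 2) array of tract-centroid (latitude, longitude) in degrees.
    svi
        Optional (S, T, 5) array of percentile covariates in [0, 1],
        ordered as :data:`SVI_COLUMNS`.
    """

    tract_ids: list[str]
    years: list[int]
    counts: np.ndarray
    centroids: np.ndarray
    svi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tract_ids = [str(t) for t in self.tract_ids]
        self.years = [int(y) for y in self.years]
        self.counts = np.asarray(self.counts)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.svi is not None:
            self.svi = np.asarray(self.svi, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def S(self) -> int:
        return len(self.tract_ids)

    @property
    def T(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        """Position of a calendar year in the panel."""
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in panel ({self.years[0]}-{self.years[-1]})")

    def time_index(self, year: int) -> int:
        """Years since the first panel year (the model time covariate)."""
        return int(year) - self.years[0]

    def counts_for_year(self, year: int) -> np.ndarray:
        return self.counts[:, self.year_index(year)]

    def svi_for_year(self, year: int) -> np.ndarray:
        if self.svi is None:
            raise ValueError("panel has no SVI covariates")
        return self.svi[:, self.year_index(year), :]

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Enforce the panel invariants; raise ``ValueError`` on violation."""
        S, T = self.S, self.T
        if S == 0 or T == 0:
            raise ValueError("panel must have at least one tract and one year")
        if len(set(self.tract_ids)) != S:
            raise ValueError("tract_ids must be unique")
        if any(b - a != 1 for a, b in zip(self.years, self.years[1:])):
            raise ValueError(f"years must be strictly consecutive, got {self.years}")
        if self.counts.shape != (S, T):
            raise ValueError(f"counts shape {self.counts.shape} != ({S}, {T})")
        if not np.issubdtype(self.counts.dtype, np.integer):
            c = self.counts
            if not np.all(np.isfinite(c)) or np.any(c != np.floor(c)):
                raise ValueError("counts must be integers (no missing cells)")
            self.counts = c.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.centroids.shape != (S, 2):
            raise ValueError(f"centroids shape {self.centroids.shape} != ({S}, 2)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.svi is not None:
            if self.svi.shape != (S, T, 5):
                raise ValueError(f"svi shape {self.svi.shape} != ({S}, {T}, 5)")
            if np.any(self.svi < 0) or np.any(self.svi > 1) or not np.all(np.isfinite(self.svi)):
                raise ValueError("svi values must lie in [0, 1]")

    def sorted_by_tract(self) -> "TractYearPanel":
        """Return a copy with tracts in sorted tract_id order."""
        order = np.argsort(np.asarray(self.tract_ids, dtype=object), kind="stable")
        return TractYearPanel(
            tract_ids=[self.tract_ids[i] for i in order],
            years=list(self.years),
            counts=self.counts[order],
            centroids=self.centroids[order],
            svi=None if self.svi is None else self.svi[order],
        )


@dataclass
class SplitSpec:
    """Year-based train / validation / test split with a look-back window W.

    ``train_years < valid_year < test_years`` must be contiguous calendar
    segments; hyperparameters are tuned on ``valid_year`` (by %BPR) and
    models are scored on ``test_years``.
    """

    train_years: list[int]
    valid_year: int
    test_years: list[int]
    lookback_W: int = 5

    def __post_init__(self) -> None:
        self.train_years = sorted(int(y) for y in self.train_years)
        self.valid_year = int(self.valid_year)
        self.test_years = sorted(int(y) for y in self.test_years)
        if self.lookback_W < 1:
            raise ValueError("lookback_W must be a positive integer")
        if not self.train_years or not self.test_years:
            raise ValueError("train_years and test_years must be non-empty")
        segs = self.train_years + [self.valid_year] + self.test_years
        if any(b - a != 1 for a, b in zip(segs, segs[1:])):
            raise ValueError(
                "split segments must be contiguous and ordered "
                f"(train {self.train_years}, valid {self.valid_year}, test {self.test_years})"
            )

    def validate_against(self, panel: TractYearPanel) -> None:
        for y in self.train_years + [self.valid_year] + self.test_years:
            if y not in panel.years:
                raise ValueError(f"split year {y} not present in panel")
        if self.train_years[0] <= panel.years[0]:
            raise ValueError(
                "every predicted year needs at least one prior observable year; "
                f"first train year {self.train_years[0]} has no history in the panel"
            )


@dataclass
class EvalConfig:
    """Run configuration for the evaluation protocol.

    Defaults mirror the study conditions: an intervention budget of
    ``k=100`` tracts and ``n_subsets=50`` resampled tract subsets.  The
    subset size may be given directly or derived from a target fraction of
    events to preserve (a uniform subset of m tracts keeps m/S of events in
    expectation).
    """

    k: int = 100
    n_subsets: int = 50
    subset_size: int | None = None
    event_fraction: float | None = None
    seed: int = 0
    models: list[dict] = field(default_factory=list)
    metrics: list[str] = field(default_factory=lambda: ["bpr", "rmse", "mae"])

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.subset_size is not None and self.subset_size < self.k:
            raise ValueError(f"k={self.k} exceeds subset_size={self.subset_size}")
        if self.event_fraction is not None and not (0 < self.event_fraction <= 1):
            raise ValueError("event_fraction must lie in (0, 1]")


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------

def read_panel_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    fill_missing_zero: bool = False,
) -> TractYearPanel:
    """Read a long-format tract-year panel CSV.

    Expected columns (renameable through ``schema``, a mapping from
    canonical name to file column name): ``tract_id, year, deaths, lat,
    lon`` and optionally the five ``svi_*`` columns.  One row per
    tract-year; duplicate (tract, year) rows are an error.  Missing
    (tract, year) combinations are an error unless ``fill_missing_zero``
    is set, in which case they become explicit zero counts.
    """
    df = pd.read_csv(path, dtype={0: str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing required columns: {missing}")
    df["tract_id"] = df["tract_id"].astype(str)
    df["year"] = df["year"].astype(int)

    dup = df.duplicated(subset=["tract_id", "year"])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise ValueError(f"duplicate (tract, year) row: ({r['tract_id']}, {r['year']})")

    deaths = df["deaths"].to_numpy()
    if np.any(~np.isfinite(deaths)) or np.any(deaths != np.floor(deaths)):
        raise ValueError("deaths must be integers")
    if np.any(deaths < 0):
        bad = df.loc[deaths < 0].iloc[0]
        raise ValueError(f"negative count for ({bad['tract_id']}, {bad['year']})")

    tract_ids = sorted(df["tract_id"].unique())
    years = list(range(int(df["year"].min()), int(df["year"].max()) + 1))
    S, T = len(tract_ids), len(years)

    n_expected = S * T
    if len(df) != n_expected and not fill_missing_zero:
        raise ValueError(
            f"panel has {len(df)} rows but S*T = {n_expected}; absent tract-years must be "
            "explicit zero rows (pass fill_missing_zero=True to opt into zero-filling)"
        )

    sidx = {t: i for i, t in enumerate(tract_ids)}
    yidx = {y: j for j, y in enumerate(years)}
    rows = df["tract_id"].map(sidx).to_numpy()
    cols = df["year"].map(yidx).to_numpy()

    counts = np.zeros((S, T), dtype=np.int64)
    counts[rows, cols] = deaths.astype(np.int64)

    centroids = np.full((S, 2), np.nan)
    centroids[rows, 0] = df["lat"].to_numpy(dtype=float)
    centroids[rows, 1] = df["lon"].to_numpy(dtype=float)
    if np.any(~np.isfinite(centroids)):
        raise ValueError("every tract needs a finite centroid in at least one row")

    svi = None
    if all(c in df.columns for c in SVI_COLUMNS):
        svi = np.zeros((S, T, 5))
        for d, c in enumerate(SVI_COLUMNS):
            svi[rows, cols, d] = df[c].to_numpy(dtype=float)
        if fill_missing_zero and len(df) != n_expected:
            # back-fill SVI of absent tract-years with the tract's mean value
            present = np.zeros((S, T), dtype=bool)
            present[rows, cols] = True
            for s in range(S):
                if present[s].any() and not present[s].all():
                    svi[s, ~present[s], :] = svi[s, present[s], :].mean(axis=0)

    return TractYearPanel(tract_ids=tract_ids, years=years, counts=counts,
                          centroids=centroids, svi=svi)


def write_panel_csv(panel: TractYearPanel, path: str | Path) -> None:
    """Write a panel as long-format CSV, rows ordered by (tract_id, year).

    Lossless round-trip with :func:`read_panel_csv` (panel tract order is
    sorted tract_id order, so read(write(p)) == p field-by-field).
    """
    p = panel.sorted_by_tract()
    S, T = p.S, p.T
    data = {
        "tract_id": np.repeat(p.tract_ids, T),
        "year": np.tile(p.years, S),
        "deaths": p.counts.ravel(),
        "lat": np.repeat(p.centroids[:, 0], T),
        "lon": np.repeat(p.centroids[:, 1], T),
    }
    if p.svi is not None:
        for d, c in enumerate(SVI_COLUMNS):
            data[c] = p.svi[:, :, d].ravel()
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


# ----------------------------------------------------------------------
# Config loading
# ----------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[EvalConfig, SplitSpec]:
    """Load run configuration from a YAML (or JSON) file.

    The file has two top-level sections: ``split`` (train_years,
    valid_year, test_years, lookback_W) and ``eval`` (k, n_subsets,
    subset_size or event_fraction, seed, models, metrics).  Omitted eval
    keys take the documented defaults (k=100, n_subsets=50).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "split" not in raw:
        raise ValueError("config must be a mapping with a 'split' section")

    sp = dict(raw["split"])
    for key in ("train_years", "valid_year", "test_years"):
        if key not in sp:
            raise ValueError(f"config split section missing '{key}'")
    tr = sp["train_years"]
    if isinstance(tr, dict):  # {start: a, end: b} shorthand
        tr = list(range(int(tr["start"]), int(tr["end"]) + 1))
    split = SplitSpec(
        train_years=tr,
        valid_year=sp["valid_year"],
        test_years=sp["test_years"],
        lookback_W=sp.get("lookback_W", 5),
    )

    ev = dict(raw.get("eval", {}))
    known = {f.name for f in dataclasses.fields(EvalConfig)}
    unknown = set(ev) - known
    if unknown:
        raise ValueError(f"unknown eval config keys: {sorted(unknown)}")
    config = EvalConfig(**ev)
    return config, split
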