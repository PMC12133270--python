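"""Synthetic tract-year count panels with known ground truth.

The generator emulates the statistical structure an annual tract-level
overdose-mortality panel exhibits — persistent spatial hotspots, slow
temporal drift, covariate effects on the log rate, and over-dispersed count
noise — while exposing every generative parameter so recovery tests can
compare estimates against truth.

Model.  For tract s with centroid c_s at year index t (years since the
first panel year),

    log lambda[s, t] = b0 + f(s) + g[s, t] + trend * t + beta' svi[s, t]

where

* ``f`` is a static spatial Gaussian field with squared-exponential
  covariance ``spatial_sd^2 * exp(-|c_s - c_s'|^2 / (2 * ell^2))`` over
  centroids (distance in lat/lon degrees) — the persistent hotspot surface;
* ``g[s, .]`` is an independent per-tract AR(1) anomaly with coefficient
  ``ar_rho`` and stationary SD fixed at ``spatial_sd / 2`` — year-to-year
  persistence of departures from the static surface;
* counts are Poisson(lambda) when ``dispersion == 0`` and negative binomial
  with mean lambda and variance lambda + dispersion * lambda^2 otherwise.

SVI covariates are generated once per tract by rank-transforming latent
scores, so each of the five columns is an exact percentile permutation of
{0, 1/(S-1), ..., 1}, and are held constant over years (the real index is
only re-published every five years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import substream
from .panel import TractYearPanel

__all__ = ["SynthParams", "GroundTruth", "generate_geometry", "generate_panel", "preset"]

#: Massachusetts-like bounding box for synthetic centroids (degrees).
_LAT_RANGE = (41.5, 42.9)
_LON_RANGE = (-73.5, -69.9)


@dataclass
class SynthParams:
    """Ground-truth generative parameters for a synthetic panel.

    ``dispersion`` is the NB2 over-dispersion alpha: variance
    mu + dispersion * mu^2; 0 selects pure Poisson noise.  ``base_log_rate``
    may be ``-inf`` as a sentinel for the all-zero-rate mode.
    """

    S: int = 1000
    T: int = 21
    base_log_rate: float = 0.0
    spatial_length_scale: float = 0.3
    spatial_sd: float = 0.8
    temporal_trend: float = 0.05
    ar_rho: float = 0.8
    svi_effects: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.1, 0.2, 0.1, 0.3])
    )
    dispersion: float = 0.3
    seed: int = 0
    first_year: int = 2000

    def __post_init__(self) -> None:
        self.svi_effects = np.asarray(self.svi_effects, dtype=float)
        if self.S < 1 or self.T < 1:
            raise ValueError("S and T must be >= 1")
        if self.spatial_length_scale <= 0:
            raise ValueError("spatial_length_scale must be > 0")
        if self.spatial_sd < 0 or self.dispersion < 0:
            raise ValueError("scale parameters must be >= 0")
        if not (0.0 <= self.ar_rho <= 1.0):
            raise ValueError("ar_rho must lie in [0, 1]")
        if self.svi_effects.shape != (5,):
            raise ValueError("svi_effects must be a 5-vector")


@dataclass
class GroundTruth:
    """True generative quantities returned alongside a synthetic panel."""

    rates: np.ndarray          # (S, T) true means lambda[s, t]
    spatial_field: np.ndarray  # (S,) static log-rate field f(s)
    anomalies: np.ndarray      # (S, T) AR(1) log-rate anomalies g[s, t]
    params: SynthParams


def generate_geometry(S: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw S tract centroids and a 5-column SVI percentile block.

    Centroids are uniform in a Massachusetts-like lat/lon box.  SVI columns
    come from rank-transforming latent tract scores (four domains sharing a
    common latent factor, composite = mean of the four), so each column is
    exactly a permutation of {0, 1/(S-1), ..., 1}; for S = 1 the percentile
    convention gives all zeros.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = substream(seed, "geometry")
    lat = rng.uniform(*_LAT_RANGE, size=S)
    lon = rng.uniform(*_LON_RANGE, size=S)
    centroids = np.column_stack([lat, lon])

    common = rng.normal(size=S)
    domains = 0.6 * common[:, None] + 0.8 * rng.normal(size=(S, 4))
    latent = np.column_stack([domains, domains.mean(axis=1)])
    if S == 1:
        svi_cols = np.zeros((1, 5))
    else:
        ranks = np.argsort(np.argsort(latent, axis=0, kind="stable"), axis=0, kind="stable")
        svi_cols = ranks / (S - 1)
    return centroids, svi_cols


def _spatial_field(centroids: np.ndarray, sd: float, length_scale: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one realisation of the squared-exponential hotspot field."""
    S = len(centroids)
    if sd == 0:
        return np.zeros(S)
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    K = sd**2 * np.exp(-d2 / (2 * length_scale**2))
    K[np.diag_indices(S)] += 1e-9 * max(sd**2, 1.0)
    L = np.linalg.cholesky(K)
    return L @ rng.normal(size=S)


def _ar1_anomaly(S: int, T: int, rho: float, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-tract stationary AR(1) path with marginal SD ``sd``."""
    g = np.zeros((S, T))
    if sd == 0:
        return g
    g[:, 0] = rng.normal(scale=sd, size=S)
    innov_sd = sd * math.sqrt(max(0.0, 1.0 - rho**2))
    for t in range(1, T):
        g[:, t] = rho * g[:, t - 1] + rng.normal(scale=innov_sd, size=S)
    return g


def generate_panel(params: SynthParams) -> tuple[TractYearPanel, GroundTruth]:
    """Generate a synthetic panel plus its ground truth.

    Fully reproducible: identical ``SynthParams`` (including seed) yield a
    bit-for-bit identical panel.
    """
    p = params
    centroids, svi_cols = generate_geometry(p.S, p.seed)
    rng = substream(p.seed, "panel")

    f = _spatial_field(centroids, p.spatial_sd, p.spatial_length_scale, rng)
    g = _ar1_anomaly(p.S, p.T, p.ar_rho, p.spatial_sd / 2.0, rng)
    t_idx = np.arange(p.T)

    log_rate = (
        p.base_log_rate
        + f[:, None]
        + g
        + p.temporal_trend * t_idx[None, :]
        + (svi_cols @ p.svi_effects)[:, None]
    )
    with np.errstate(over="ignore"):
        rates = np.exp(log_rate)
    if np.any(np.isnan(rates)) or np.any(np.isinf(rates)):
        raise ValueError("non-finite rate lambda; generative parameters too extreme")

    if p.dispersion == 0:
        counts = rng.poisson(rates)
    else:
        # NB2 via n = 1/alpha, p = 1 / (1 + alpha * mu)
        n = 1.0 / p.dispersion
        prob = 1.0 / (1.0 + p.dispersion * rates)
        counts = rng.negative_binomial(n, prob)

    tract_ids = [f"{25000000000 + i:011d}" for i in range(p.S)]
    svi = np.repeat(svi_cols[:, None, :], p.T, axis=1)
    panel = TractYearPanel(
        tract_ids=tract_ids,
        years=list(range(p.first_year, p.first_year + p.T)),
        counts=counts.astype(np.int64),
        centroids=centroids,
        svi=svi,
    )
    truth = GroundTruth(rates=rates, spatial_field=f, anomalies=g, params=p)
    return panel, truth


def _base_rate_for_mean(mean_count: float, params: SynthParams) -> float:
    """Intercept making the panel-wide expected count approx ``mean_count``.

    Uses the lognormal corrections for the Gaussian field and anomaly
    (E exp(f) = exp(var/2)), the mid-panel trend level, and the exact
    expectation of exp(beta * u) for u ~ Uniform(0, 1) per SVI column.
    """
    var = params.spatial_sd**2 + (params.spatial_sd / 2.0) ** 2
    adj = 0.5 * var + params.temporal_trend * (params.T - 1) / 2.0
    for b in params.svi_effects:
        if b != 0:
            adj += math.log((math.exp(b) - 1.0) / b)
    return math.log(mean_count) - adj


_PRESETS = {
    # Emulates the sparsity of a state-scale panel: ~1000-1600 tracts over
    # two decades with a panel-wide mean count around 1.2 per tract-year.
    "massachusetts-like": dict(S=1000, T=21, mean_count=1.2, spatial_sd=0.8,
                               spatial_length_scale=0.3, temporal_trend=0.05,
                               ar_rho=0.8, dispersion=0.3, first_year=2000),
    # Small, strongly persistent panel used for fast end-to-end checks.
    "persistent-small": dict(S=200, T=12, mean_count=1.5, spatial_sd=1.0,
                             spatial_length_scale=0.3, temporal_trend=0.05,
                             ar_rho=0.95, dispersion=0.2, first_year=2009),
}


def preset(name: str, seed: int = 0, **overrides) -> SynthParams:
    """Return the named SynthParams preset (seed and overrides applied)."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    cfg = dict(_PRESETS[name])
    mean_count = cfg.pop("mean_count")
    params = SynthParams(seed=seed, base_log_rate=0.0, **cfg)
    params = replace(params, base_log_rate=_base_rate_for_mean(mean_count, params))
    if overrides:
        params = replace(params, **overrides)
    return params
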