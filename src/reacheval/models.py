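"""Count-regression cores and the forecasting model suite.

Two layers live here.

The regression layer follows the Model/Results idiom: construct
:class:`PoissonRegression` or :class:`NegativeBinomialRegression` from an
endog vector and exog matrix, call ``fit()``, and receive a results object
carrying the coefficient vector, standard errors, log-likelihood and a
``summary()`` table.  The Poisson fit is ridge-stabilised IRLS with
step-halving; the NB2 fit alternates IRLS coefficient updates with a 1-D
profile maximisation of the dispersion alpha (variance mu + alpha * mu^2,
alpha -> 0 recovering Poisson).

The forecasting layer wraps those cores (plus simple baselines and a
gradient-boosted-trees ensemble) behind one fit/predict contract so the
evaluation protocol is model-agnostic: ``family.fit(panel, split)`` trains
on the training years, ``.predict(panel, year)`` produces S non-negative
predicted counts for a year, rebuilding features from observed counts
through the prior year (one-step-ahead rolling forecasts with parameters
frozen after training).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .features import (
    FeatureMatrix,
    Standardizer,
    assemble_design_matrix,
    build_history_features,
    build_spatial_lag_features,
)
from .panel import SplitSpec, TractYearPanel

__all__ = [
    "PoissonRegression",
    "PoissonRegressionResults",
    "NegativeBinomialRegression",
    "NegativeBinomialRegressionResults",
    "ForecastSet",
    "AllZeros",
    "HistoricalAverage",
    "PoissonGLMForecaster",
    "NegBinSpatialLagForecaster",
    "GradientBoostedTreesForecaster",
    "MODEL_REGISTRY",
    "make_model",
    "forecast_test_years",
    "read_predictions_csv",
    "write_predictions_csv",
]

_ETA_CLIP = 30.0  # |linear predictor| bound guarding exp overflow


def _add_const(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


# ======================================================================
# Poisson regression (ridge-stabilised IRLS)
# ======================================================================

class PoissonRegression:
    """Poisson log-linear model y ~ Poisson(exp(theta' x)).

    An intercept column is prepended automatically.  ``ridge`` adds an L2
    penalty ridge * ||theta_non-intercept||^2 to the negative
    log-likelihood for numerical stability on sparse panels.
    """

    def __init__(self, endog, exog, ridge: float = 1e-6,
                 column_names: Sequence[str] | None = None) -> None:
        self.endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim != 2 or exog.shape[0] != len(self.endog):
            raise ValueError("exog must be (n, p) aligned with endog")
        if np.any(self.endog < 0) or not np.all(np.isfinite(self.endog)):
            raise ValueError("endog must be finite and >= 0")
        if ridge < 0:
            raise ValueError("ridge must be >= 0")
        self.exog = _add_const(exog)
        self.ridge = float(ridge)
        names = list(column_names) if column_names is not None else [
            f"x{j}" for j in range(exog.shape[1])
        ]
        self.column_names = ["const"] + names

    # penalty mask: intercept unpenalised
    @property
    def _pen(self) -> np.ndarray:
        m = np.full(self.exog.shape[1], self.ridge)
        m[0] = 0.0
        return m

    def loglike(self, params: np.ndarray) -> float:
        eta = np.clip(self.exog @ params, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        return float(np.sum(self.endog * eta - mu - gammaln(self.endog + 1)))

    def _penalized_ll(self, params: np.ndarray) -> float:
        return self.loglike(params) - float(self._pen @ params**2)

    def score(self, params: np.ndarray) -> np.ndarray:
        eta = np.clip(self.exog @ params, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        return self.exog.T @ (self.endog - mu) - 2 * self._pen * params

    def fit(self, maxiter: int = 100, gtol: float = 1e-8,
            start_params: np.ndarray | None = None) -> "PoissonRegressionResults":
        y = self.endog
        if y.sum() == 0:
            raise ValueError(
                "all-zero response: the Poisson intercept is unbounded below "
                "(the MLE does not exist); increase ridge does not help since "
                "the intercept is unpenalised"
            )
        p = self.exog.shape[1]
        theta = np.zeros(p) if start_params is None else np.asarray(start_params, float).copy()
        if start_params is None:
            theta[0] = math.log(max(y.mean(), 1e-12))
        ll = self._penalized_ll(theta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            grad = self.score(theta)
            if np.max(np.abs(grad)) < gtol:
                converged = True
                break
            eta = np.clip(self.exog @ theta, -_ETA_CLIP, _ETA_CLIP)
            w = np.exp(eta)
            H = (self.exog * w[:, None]).T @ self.exog
            H[np.diag_indices(p)] += 2 * self._pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                raise ValueError("singular IRLS system; add ridge > 0") from None
            # step-halving keeps the penalized log-likelihood non-decreasing
            alpha = 1.0
            for _ in range(40):
                cand = theta + alpha * step
                ll_cand = self._penalized_ll(cand)
                if np.isfinite(ll_cand) and ll_cand >= ll - 1e-12:
                    break
                alpha /= 2.0
            else:
                raise ValueError("IRLS diverged (non-finite update); increase ridge")
            theta, ll = cand, ll_cand
            if not np.all(np.isfinite(theta)):
                raise ValueError("IRLS diverged (non-finite theta); increase ridge")
        else:
            grad = self.score(theta)
            converged = bool(np.max(np.abs(grad)) < gtol)
        return PoissonRegressionResults(self, theta, self.loglike(theta), it, converged)


@dataclass
class PoissonRegressionResults:
    """Fitted Poisson regression: coefficients, likelihood and predictions."""

    model: PoissonRegression
    params: np.ndarray
    llf: float
    niter: int
    converged: bool

    def predict(self, exog) -> np.ndarray:
        """Predicted means exp(theta' x); exog without the intercept column."""
        X = _add_const(np.asarray(exog, dtype=float))
        return np.exp(np.clip(X @ self.params, -_ETA_CLIP, _ETA_CLIP))

    def bse(self) -> np.ndarray:
        """Asymptotic standard errors from the observed Fisher information."""
        eta = np.clip(self.model.exog @ self.params, -_ETA_CLIP, _ETA_CLIP)
        w = np.exp(eta)
        H = (self.model.exog * w[:, None]).T @ self.model.exog
        H[np.diag_indices(len(self.params))] += 2 * self.model._pen
        return np.sqrt(np.diag(np.linalg.inv(H)))

    def summary(self) -> str:
        lines = [
            "Poisson regression (log link, ridge-stabilised IRLS)",
            f"  n = {len(self.model.endog)}, llf = {self.llf:.4f}, "
            f"iterations = {self.niter}, converged = {self.converged}",
            f"  {'term':<20} {'coef':>12} {'std err':>12}",
        ]
        se = self.bse()
        for name, b, s in zip(self.model.column_names, self.params, se):
            lines.append(f"  {name:<20} {b:>12.6f} {s:>12.6f}")
        return "\n".join(lines)


# ======================================================================
# Negative binomial (NB2) regression
# ======================================================================

_ALPHA_FLOOR = 1e-8
_ALPHA_CEIL = 100.0


def _nb2_loglike(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < _ALPHA_FLOOR:
        alpha = _ALPHA_FLOOR
    r = 1.0 / alpha
    mu = np.clip(mu, 1e-12, None)
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    ))


class NegativeBinomialRegression:
    """NB2 regression: mean exp(theta' x), variance mu + alpha * mu^2.

    Fitted by alternating a Fisher-scoring theta update at fixed alpha with
    a bounded 1-D profile-likelihood maximisation over alpha, until the
    log-likelihood improves by less than ``tol``.  alpha is floored at
    1e-8, the Poisson limit.
    """

    def __init__(self, endog, exog, ridge: float = 1e-6,
                 column_names: Sequence[str] | None = None) -> None:
        self._pois = PoissonRegression(endog, exog, ridge=ridge, column_names=column_names)
        self.endog = self._pois.endog
        self.exog = self._pois.exog
        self.ridge = ridge
        self.column_names = self._pois.column_names

    def _theta_step(self, theta: np.ndarray, alpha: float, n_inner: int = 50,
                    gtol: float = 1e-8) -> np.ndarray:
        y, X = self.endog, self.exog
        pen = self._pois._pen
        p = X.shape[1]
        for _ in range(n_inner):
            eta = np.clip(X @ theta, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta)
            denom = 1.0 + alpha * mu
            grad = X.T @ ((y - mu) / denom) - 2 * pen * theta
            if np.max(np.abs(grad)) < gtol:
                break
            w = mu / denom
            H = (X * w[:, None]).T @ X
            H[np.diag_indices(p)] += 2 * pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                raise ValueError("singular NB scoring system; add ridge > 0") from None
            ll0 = _nb2_loglike(y, mu, alpha) - float(pen @ theta**2)
            a = 1.0
            for _ in range(40):
                cand = theta + a * step
                mu_c = np.exp(np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP))
                ll_c = _nb2_loglike(y, mu_c, alpha) - float(pen @ cand**2)
                if np.isfinite(ll_c) and ll_c >= ll0 - 1e-12:
                    break
                a /= 2.0
            theta = cand
        return theta

    def fit(self, maxiter_outer: int = 200, tol: float = 1e-7
            ) -> "NegativeBinomialRegressionResults":
        y, X = self.endog, self.exog
        start = self._pois.fit()
        theta = start.params.copy()
        alpha = 0.1
        trace: list[float] = []
        ll_prev = -np.inf
        converged = False
        for it in range(1, maxiter_outer + 1):
            theta = self._theta_step(theta, alpha)
            mu = np.exp(np.clip(X @ theta, -_ETA_CLIP, _ETA_CLIP))

            res = minimize_scalar(
                lambda la: -_nb2_loglike(y, mu, math.exp(la)),
                bounds=(math.log(_ALPHA_FLOOR), math.log(_ALPHA_CEIL)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            alpha = max(math.exp(res.x), _ALPHA_FLOOR)
            ll = _nb2_loglike(y, mu, alpha)
            trace.append(ll)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        if not converged:
            raise ValueError(
                "NB2 alternating maximisation did not converge in "
                f"{maxiter_outer} outer iterations; log-likelihood trace tail: "
                f"{[round(v, 6) for v in trace[-5:]]}"
            )
        return NegativeBinomialRegressionResults(self, theta, alpha, ll, it, converged)


@dataclass
class NegativeBinomialRegressionResults:
    model: NegativeBinomialRegression
    params: np.ndarray
    alpha: float
    llf: float
    niter: int
    converged: bool

    def predict(self, exog) -> np.ndarray:
        X = _add_const(np.asarray(exog, dtype=float))
        return np.exp(np.clip(X @ self.params, -_ETA_CLIP, _ETA_CLIP))

    def summary(self) -> str:
        lines = [
            "Negative binomial (NB2) regression, variance mu + alpha*mu^2",
            f"  n = {len(self.model.endog)}, llf = {self.llf:.4f}, "
            f"alpha = {self.alpha:.6f}, outer iterations = {self.niter}",
            f"  {'term':<20} {'coef':>12}",
        ]
        for name, b in zip(self.model.column_names, self.params):
            lines.append(f"  {name:<20} {b:>12.6f}")
        return "\n".join(lines)


# ======================================================================
# Forecasting layer
# ======================================================================

@dataclass
class ForecastSet:
    """Per-test-year prediction vectors from one model, in panel tract order."""

    model_name: str
    predictions: dict[int, np.ndarray]
    uninformative: bool = False

    def __post_init__(self) -> None:
        for year, v in self.predictions.items():
            v = np.asarray(v, dtype=float)
            if np.any(~np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"predictions for year {year} must be finite and >= 0")
            self.predictions[year] = v


class ForecastModel:
    """Common fit/predict contract for all forecasting families."""

    name: str = "base"
    uninformative: bool = False

    def __init__(self, **hyperparams) -> None:
        self.hyperparams = hyperparams

    def fit(self, panel: TractYearPanel, split: SplitSpec) -> "ForecastModel":
        return self

    def predict(self, panel: TractYearPanel, year: int) -> np.ndarray:
        raise NotImplementedError


class AllZeros(ForecastModel):
    """Predicts zero everywhere; ranks all tracts equally high risk.

    Flagged uninformative so the evaluation layer scores its reach by
    averaging over uniformly random K-subsets rather than by its (tied)
    top-K selection.
    """

    name = "all_zeros"
    uninformative = True

    def predict(self, panel: TractYearPanel, year: int) -> np.ndarray:
        return np.zeros(panel.S)


class HistoricalAverage(ForecastModel):
    """Mean of each tract's counts over the preceding W years.

    The look-back length W is the only hyperparameter; no fitting beyond
    storing it.  Prediction for (s, t) uses observed counts y[s, t-W..t-1].
    """

    name = "historical_average"

    def __init__(self, W: int = 4) -> None:
        if W < 1:
            raise ValueError("W must be >= 1")
        super().__init__(W=W)
        self.W = W

    def predict(self, panel: TractYearPanel, year: int) -> np.ndarray:
        j = panel.year_index(year)
        if j < self.W:
            raise ValueError(
                f"historical average W={self.W} exceeds available history before {year}"
            )
        return panel.counts[:, j - self.W:j].mean(axis=1)


class _FeatureModelMixin:
    """Shared feature assembly for regression/tree forecasters."""

    W: int
    include_svi: bool
    include_geo_time: bool
    n_neighbors: int | None
    _standardizer: Standardizer | None

    def _blocks(self, panel: TractYearPanel, years: Sequence[int]) -> list[FeatureMatrix]:
        blocks = [build_history_features(panel, years, self.W)]
        if self.n_neighbors is not None:
            blocks.append(build_spatial_lag_features(panel, years, self.n_neighbors))
        return blocks

    def _design(self, panel: TractYearPanel, years: Sequence[int],
                fit_standardizer: bool) -> FeatureMatrix:
        fm, std = assemble_design_matrix(
            self._blocks(panel, years),
            panel=panel,
            include_svi=self.include_svi,
            include_geo_time=self.include_geo_time,
            standardize=fit_standardizer,
            standardizer=None if fit_standardizer else self._standardizer,
        )
        if fit_standardizer:
            self._standardizer = std
        return fm

    def _train_years(self, panel: TractYearPanel, split: SplitSpec) -> list[int]:
        years = [y for y in split.train_years if panel.time_index(y) >= self.W]
        if not years:
            raise ValueError(
                f"no training year has W={self.W} years of prior history in the panel"
            )
        return years


class PoissonGLMForecaster(_FeatureModelMixin, ForecastModel):
    """Poisson GLM on lagged counts, geography, time and optional SVI."""

    name = "poisson_glm"

    def __init__(self, W: int = 5, include_svi: bool = True,
                 include_geo_time: bool = True, ridge: float = 1e-6) -> None:
        super().__init__(W=W, include_svi=include_svi,
                         include_geo_time=include_geo_time, ridge=ridge)
        self.W = W
        self.include_svi = include_svi
        self.include_geo_time = include_geo_time
        self.ridge = ridge
        self.n_neighbors = None
        self._standardizer = None
        self.results_: PoissonRegressionResults | None = None

    def fit(self, panel: TractYearPanel, split: SplitSpec) -> "PoissonGLMForecaster":
        fm = self._design(panel, self._train_years(panel, split), fit_standardizer=True)
        self.results_ = PoissonRegression(
            fm.y, fm.X, ridge=self.ridge, column_names=fm.columns
        ).fit()
        return self

    def predict(self, panel: TractYearPanel, year: int) -> np.ndarray:
        if self.results_ is None:
            raise RuntimeError("model not fitted")
        fm = self._design(panel, [year], fit_standardizer=False)
        return self.results_.predict(fm.X)


class NegBinSpatialLagForecaster(_FeatureModelMixin, ForecastModel):
    """NB2 regression with spatially lagged neighbour counts (NBSpLag).

    Each tract's design row includes the mean prior-year count of its
    ``n_neighbors`` nearest tracts, so predictions are informed by spatial
    neighbours; over-dispersion is estimated jointly with the coefficients.
    """

    name = "nb_splag"

    def __init__(self, W: int = 5, n_neighbors: int = 5, include_svi: bool = True,
                 include_geo_time: bool = True, ridge: float = 1e-6) -> None:
        super().__init__(W=W, n_neighbors=n_neighbors, include_svi=include_svi,
                         include_geo_time=include_geo_time, ridge=ridge)
        self.W = W
        self.n_neighbors = n_neighbors
        self.include_svi = include_svi
        self.include_geo_time = include_geo_time
        self.ridge = ridge
        self._standardizer = None
        self.results_: NegativeBinomialRegressionResults | None = None

    def fit(self, panel: TractYearPanel, split: SplitSpec) -> "NegBinSpatialLagForecaster":
        fm = self._design(panel, self._train_years(panel, split), fit_standardizer=True)
        self.results_ = NegativeBinomialRegression(
            fm.y, fm.X, ridge=self.ridge, column_names=fm.columns
        ).fit()
        return self

    def predict(self, panel: TractYearPanel, year: int) -> np.ndarray:
        if self.results_ is None:
            raise RuntimeError("model not fitted")
        fm = self._design(panel, [year], fit_standardizer=False)
        return self.results_.predict(fm.X)


class GradientBoostedTreesForecaster(_FeatureModelMixin, ForecastModel):
    """Least-squares gradient-boosted regression trees on the same features.

    Delegates the ensemble to scikit-learn; this class owns the contract:
    deterministic given seed and hyperparameters, raw predictions clipped
    at zero.
    """

    name = "gbt"

    def __init__(self, n_trees: int = 100, max_depth: int = 3,
                 learning_rate: float = 0.1, W: int = 5, include_svi: bool = True,
                 include_geo_time: bool = True, seed: int = 0) -> None:
        if n_trees < 1 or max_depth < 1 or not (0 < learning_rate <= 1):
            raise ValueError("invalid GBT hyperparameters")
        super().__init__(n_trees=n_trees, max_depth=max_depth,
                         learning_rate=learning_rate, W=W, include_svi=include_svi,
                         include_geo_time=include_geo_time, seed=seed)
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.W = W
        self.include_svi = include_svi
        self.include_geo_time = include_geo_time
        self.seed = seed
        self.n_neighbors = None
        self._standardizer = None
        self._est = None

    def fit(self, panel: TractYearPanel, split: SplitSpec) -> "GradientBoostedTreesForecaster":
        from sklearn.ensemble import GradientBoostingRegressor

        fm = self._design(panel, self._train_years(panel, split), fit_standardizer=True)
        self._est = GradientBoostingRegressor(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.seed,
        ).fit(fm.X, fm.y)
        return self

    def predict(self, panel: TractYearPanel, year: int) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("model not fitted")
        fm = self._design(panel, [year], fit_standardizer=False)
        return np.clip(self._est.predict(fm.X), 0.0, None)


def _stub(name: str, hint: str) -> Callable[..., ForecastModel]:
    def factory(**_kw) -> ForecastModel:
        raise NotImplementedError(
            f"{name} is not implemented in this package ({hint}); score externally "
            "produced forecasts via a predictions CSV (tract_id, year, y_pred) instead"
        )
    return factory


#: name -> constructor; stub entries exist so comparison tables can still be
#: assembled from externally supplied prediction CSVs for those methods.
MODEL_REGISTRY: dict[str, Callable[..., ForecastModel]] = {
    "all_zeros": AllZeros,
    "historical_average": HistoricalAverage,
    "poisson_glm": PoissonGLMForecaster,
    "nb_splag": NegBinSpatialLagForecaster,
    "gbt": GradientBoostedTreesForecaster,
    "gp": _stub("gp", "Gaussian Process forecaster"),
    "bst": _stub("bst", "Bayesian spatiotemporal Markov-random-field model"),
    "castnet": _stub("castnet", "attention-based neural forecaster"),
}


def make_model(name: str, **hyperparams) -> ForecastModel:
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}")
    return MODEL_REGISTRY[name](**hyperparams)


def forecast_test_years(
    model: ForecastModel,
    panel: TractYearPanel,
    split: SplitSpec,
    refit_each_year: bool = False,
) -> ForecastSet:
    """Fit on training years, then roll one-step-ahead over the test years.

    Parameters are frozen after training by default; for each test year t
    features are rebuilt from observed counts through t-1, so the second
    test year always conditions on the first year's *observed* counts.
    With ``refit_each_year`` the model is refit with the split's training
    window extended to t-1 before each test year.
    """
    split.validate_against(panel)
    fitted = model.fit(panel, split)
    preds: dict[int, np.ndarray] = {}
    for year in split.test_years:
        if refit_each_year and year != split.test_years[0]:
            extended = SplitSpec(
                train_years=list(range(split.train_years[0], year - 1)),
                valid_year=year - 1,
                test_years=[year],
                lookback_W=split.lookback_W,
            )
            fitted = model.fit(panel, extended)
        preds[year] = np.asarray(fitted.predict(panel, year), dtype=float)
    return ForecastSet(model_name=model.name, predictions=preds,
                       uninformative=model.uninformative)


# ----------------------------------------------------------------------
# Prediction exchange CSV (for external models: GP / BST / CASTNet ...)
# ----------------------------------------------------------------------

def read_predictions_csv(path, panel: TractYearPanel, model_name: str,
                         uninformative: bool = False) -> ForecastSet:
    """Read externally produced forecasts (columns tract_id, year, y_pred).

    Vectors are aligned to the panel's tract order; every (tract, year)
    pair for the years present must appear exactly once.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"tract_id": str})
    need = {"tract_id", "year", "y_pred"}
    if not need <= set(df.columns):
        raise ValueError(f"predictions CSV needs columns {sorted(need)}")
    sidx = {t: i for i, t in enumerate(panel.tract_ids)}
    preds: dict[int, np.ndarray] = {}
    for year, grp in df.groupby("year"):
        v = np.full(panel.S, np.nan)
        for tid, val in zip(grp["tract_id"], grp["y_pred"]):
            if tid not in sidx:
                raise ValueError(f"unknown tract_id {tid!r} in predictions CSV")
            v[sidx[tid]] = val
        if np.any(np.isnan(v)):
            missing = [panel.tract_ids[i] for i in np.flatnonzero(np.isnan(v))][:3]
            raise ValueError(f"year {year}: missing predictions for tracts {missing}...")
        preds[int(year)] = v
    return ForecastSet(model_name=model_name, predictions=preds,
                       uninformative=uninformative)


def write_predictions_csv(forecasts: ForecastSet, panel: TractYearPanel, path) -> None:
    import pandas as pd

    rows = []
    for year in sorted(forecasts.predictions):
        v = forecasts.predictions[year]
        rows.append(pd.DataFrame({
            "tract_id": panel.tract_ids, "year": year, "y_pred": v,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
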