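"""Evaluation protocol: splits, BPR-based tuning, tract resampling, tables.

The protocol mirrors how forecast suites are compared for intervention
planning: models are tuned to maximise %BPR on a validation year, scored
on held-out test years, and every metric is summarised over many resampled
tract subsets (sampling without replacement) so that the min-max interval
across subsets expresses ranking uncertainty.  A model whose interval
overlaps the best model's mean is marked indistinguishable from the best.

The orchestration follows the Model/Results idiom:
:class:`ReachEvaluation` is built from a panel, a split and a config; its
``run()`` returns an :class:`EvaluationResults` carrying per-model metric
summaries, the true-total-in-top-K tally, the comparison table, a
``summary()`` string and plotting/saving helpers.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .metrics import bpr, expected_random_bpr, mae, rmse, top_k_indices, top_k_sum
from .models import ForecastModel, ForecastSet, forecast_test_years, make_model
from .panel import EvalConfig, SplitSpec, TractYearPanel

__all__ = [
    "MetricSummary",
    "ComparisonTable",
    "ReachEvaluation",
    "EvaluationResults",
    "make_split",
    "tune_hyperparameters",
    "draw_tract_subsets",
    "resolve_subset_size",
    "resample_metrics",
    "true_total_in_top_k",
    "build_comparison_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: canonical ordering used to prefer the simplest configuration on ties
_SIMPLICITY_ORDER = ("W", "n_trees", "max_depth", "n_neighbors", "learning_rate", "ridge")


@dataclass
class MetricSummary:
    """Mean and min-max interval of a metric over resampled tract subsets."""

    name: str
    values: np.ndarray
    per_year: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) == 0:
            raise ValueError("metric summary needs at least one sample")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def n_samples(self) -> int:
        return len(self.values)


@dataclass
class ComparisonTable:
    """One row per model: true-total tally plus metric summaries and marks."""

    model_names: list[str]
    true_totals: dict[str, float]
    summaries: dict[str, dict[str, MetricSummary]]  # model -> metric -> summary
    best_marks: dict[str, set[str]] = field(default_factory=dict)  # metric -> models
    best_model: dict[str, str] = field(default_factory=dict)       # metric -> model

    _HIGHER_BETTER = {"bpr"}
    _FMT = {"bpr": ("%BPR", 100.0, 1), "rmse": ("RMSE", 1.0, 2), "mae": ("MAE", 1.0, 2)}

    def compute_marks(self) -> None:
        metrics = list(next(iter(self.summaries.values())).keys())
        for m in metrics:
            means = {name: self.summaries[name][m].mean for name in self.model_names}
            if m in self._HIGHER_BETTER:
                best = max(self.model_names, key=lambda n: means[n])
            else:
                best = min(self.model_names, key=lambda n: means[n])
            best_mean = means[best]
            marked = {
                name for name in self.model_names
                if self.summaries[name][m].min <= best_mean <= self.summaries[name][m].max
            }
            marked.add(best)
            self.best_model[m] = best
            self.best_marks[m] = marked

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name in self.model_names:
            row: dict = {"model": name, "true_total_top_k": round(self.true_totals[name], 1)}
            for m, s in self.summaries[name].items():
                label, scale, nd = self._FMT.get(m, (m, 1.0, 3))
                row[f"{label}_mean"] = round(s.mean * scale, nd)
                row[f"{label}_min"] = round(s.min * scale, nd)
                row[f"{label}_max"] = round(s.max * scale, nd)
                row[f"{label}_best"] = name in self.best_marks.get(m, set())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        metrics = list(next(iter(self.summaries.values())).keys())
        headers = ["model", "true_total_top_k"]
        for m in metrics:
            headers.append(self._FMT.get(m, (m, 1.0, 3))[0])
        lines = []
        body = []
        for name in self.model_names:
            cells = [name, f"{self.true_totals[name]:.1f}"]
            for m in metrics:
                label, scale, nd = self._FMT.get(m, (m, 1.0, 3))
                s = self.summaries[name][m]
                star = "*" if name in self.best_marks.get(m, set()) else ""
                cells.append(
                    f"{s.mean * scale:.{nd}f} ({s.min * scale:.{nd}f}-{s.max * scale:.{nd}f}){star}"
                )
            body.append(cells)
        widths = [max(len(h), *(len(r[i]) for r in body)) for i, h in enumerate(headers)]
        lines.append("  ".join(h.ljust(w) for h, w in zip(headers, widths)))
        lines.append("  ".join("-" * w for w in widths))
        for r in body:
            lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
        lines.append("* best mean for the metric, or interval overlapping the best mean")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Protocol pieces
# ----------------------------------------------------------------------

def make_split(panel: TractYearPanel, train_years: Sequence[int], valid_year: int,
               test_years: Sequence[int], W: int) -> SplitSpec:
    """Validate and return a year-based split against a panel."""
    split = SplitSpec(train_years=list(train_years), valid_year=valid_year,
                      test_years=list(test_years), lookback_W=W)
    split.validate_against(panel)
    return split


def _expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _simplicity_key(hp: Mapping) -> tuple:
    head = tuple(hp.get(k, 0) for k in _SIMPLICITY_ORDER)
    return head + tuple(sorted((k, repr(v)) for k, v in hp.items()))


def tune_hyperparameters(
    model_name: str,
    grid: Mapping[str, Sequence],
    panel: TractYearPanel,
    split: SplitSpec,
    k: int,
    seed: int = 0,
) -> dict:
    """Pick the grid point maximising full-panel %BPR on the validation year.

    Each candidate is fitted on the training years and scored by the BPR of
    its top-k validation-year predictions (fixed tie-break stream).  Ties go
    to the simplest configuration (smallest W / fewest trees / shallowest
    depth), then lexicographically.  Candidates that fail to fit are
    skipped with a warning; if all fail, an error is raised.
    """
    candidates = _expand_grid(grid)
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    # fit() only reads the training years, so the original split is safe here:
    # the model never sees validation- or test-year targets while fitting
    y_valid = panel.counts_for_year(split.valid_year)
    scored: list[tuple[float, tuple, dict]] = []
    for hp in candidates:
        rng = substream(seed, "tune", model_name, json.dumps(hp, sort_keys=True, default=str))
        try:
            model = make_model(model_name, **hp)
            fitted = model.fit(panel, split)
            pred = fitted.predict(panel, split.valid_year)
            iset = top_k_indices(pred, k, rng=rng, provenance=f"tune:{model_name}")
            score = bpr(y_valid, iset)
        except NotImplementedError:
            raise
        except Exception as exc:  # noqa: BLE001 - grid points may legitimately fail
            logger.warning("grid point %s failed for %s: %s", hp, model_name, exc)
            continue
        scored.append((score, _simplicity_key(hp), hp))
    if not scored:
        raise ValueError(f"every grid point failed to fit for model {model_name!r}")
    scored.sort(key=lambda t: (-t[0], t[1]))
    return scored[0][2]


def resolve_subset_size(panel: TractYearPanel, event_fraction: float,
                        test_years: Sequence[int] | None = None) -> int:
    """Subset size preserving a target fraction of events in an average sample.

    A uniform subset of m tracts keeps m/S of events in expectation, so the
    size is simply round(event_fraction * S); an explicit subset_size in
    the config always overrides this heuristic.
    """
    if not (0 < event_fraction <= 1):
        raise ValueError("event_fraction must lie in (0, 1]")
    return int(round(event_fraction * panel.S))


def draw_tract_subsets(S: int, subset_size: int, n_subsets: int,
                       seed: int) -> list[np.ndarray]:
    """n_subsets sorted index arrays sampled uniformly without replacement."""
    if subset_size > S:
        raise ValueError(f"subset_size {subset_size} exceeds S={S}")
    if subset_size < 1 or n_subsets < 1:
        raise ValueError("subset_size and n_subsets must be >= 1")
    rng = substream(seed, "subsets")
    return [np.sort(rng.choice(S, size=subset_size, replace=False))
            for _ in range(n_subsets)]


_METRIC_FNS = {"rmse": rmse, "mae": mae}


def resample_metrics(
    y_true_by_year: Mapping[int, np.ndarray],
    forecasts: ForecastSet,
    subsets: Sequence[np.ndarray],
    k: int,
    metrics: Sequence[str] = ("bpr", "rmse", "mae"),
    rng: np.random.Generator | None = None,
) -> dict[str, MetricSummary]:
    """Per-(year, subset) metric values pooled into mean / min-max summaries.

    For each test year and tract subset, observed counts and predictions
    are restricted to the subset, the model's top-k is formed *within* the
    subset, and each metric computed; the year x subset values are pooled
    into one summary per metric.  Uninformative models take the exact
    random-selection expectation for BPR within each subset.
    """
    if rng is None:
        rng = np.random.default_rng()
    for sub in subsets:
        if k > len(sub):
            raise ValueError(f"k={k} exceeds subset size {len(sub)}")
    values: dict[str, dict[int, list[float]]] = {m: {} for m in metrics}
    for year in sorted(forecasts.predictions):
        y_true = np.asarray(y_true_by_year[year], dtype=float)
        y_pred = forecasts.predictions[year]
        if len(y_true) != len(y_pred):
            raise ValueError("forecasts not aligned to the panel tract order")
        for sub in subsets:
            yt, yp = y_true[sub], y_pred[sub]
            for m in metrics:
                if m == "bpr":
                    if forecasts.uninformative:
                        val = expected_random_bpr(yt, k, n_draws=1, rng=rng).closed_form
                    else:
                        iset = top_k_indices(yp, k, rng=rng,
                                             provenance=f"resample:{forecasts.model_name}")
                        val = bpr(yt, iset)
                elif m in _METRIC_FNS:
                    val = _METRIC_FNS[m](yt, yp)
                else:
                    raise KeyError(f"unknown metric {m!r}")
                values[m].setdefault(year, []).append(val)
    return {
        m: MetricSummary(
            name=m,
            values=np.concatenate([np.asarray(v) for v in per_year.values()]),
            per_year={y: np.asarray(v) for y, v in per_year.items()},
        )
        for m, per_year in values.items()
    }


def true_total_in_top_k(
    y_true_by_year: Mapping[int, np.ndarray],
    forecasts: ForecastSet,
    k: int,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[int, float]]:
    """Observed events inside the model's full-set top-k, averaged over years.

    Returns (mean across test years, per-year values).  Uninformative
    models take the exact expectation (k/S) * total events of a uniformly
    random K-subset.
    """
    if rng is None:
        rng = np.random.default_rng()
    per_year: dict[int, float] = {}
    for year in sorted(forecasts.predictions):
        y_true = np.asarray(y_true_by_year[year], dtype=float)
        if forecasts.uninformative:
            per_year[year] = float(k / len(y_true) * y_true.sum())
        else:
            iset = top_k_indices(forecasts.predictions[year], k, rng=rng,
                                 provenance=f"tally:{forecasts.model_name}")
            per_year[year] = float(y_true[np.asarray(iset.indices)].sum())
    return float(np.mean(list(per_year.values()))), per_year


def build_comparison_table(
    summaries: Mapping[str, Mapping[str, MetricSummary]],
    true_totals: Mapping[str, float],
) -> ComparisonTable:
    """Assemble the model-comparison table and apply the best-marking rule.

    Per metric the best mean is found (max for BPR, min for error metrics);
    the best model is marked along with every model whose min-max interval
    contains that best mean.
    """
    if not summaries:
        raise ValueError("need at least one model")
    table = ComparisonTable(
        model_names=list(summaries.keys()),
        true_totals=dict(true_totals),
        summaries={n: dict(s) for n, s in summaries.items()},
    )
    table.compute_marks()
    return table


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

class ReachEvaluation:
    """End-to-end evaluation of a model suite on one panel.

    Parameters
    ----------
    panel
        The tract-year panel to evaluate on.
    split
        Year-based train/validation/test split.
    config
        Budget k, resampling settings, seed and the model list, each model
        given as ``{"name": ..., "grid": {hyperparam: [candidates]}}``.
    external_forecasts
        Optional pre-computed :class:`ForecastSet` objects (e.g. from a
        predictions CSV for models not implemented here); they skip tuning
        and fitting but are scored identically.
    """

    def __init__(self, panel: TractYearPanel, split: SplitSpec, config: EvalConfig,
                 external_forecasts: Sequence[ForecastSet] = ()) -> None:
        split.validate_against(panel)
        if config.k > panel.S:
            raise ValueError(f"intervention budget k={config.k} exceeds S={panel.S}")
        self.panel = panel
        self.split = split
        self.config = config
        self.external_forecasts = list(external_forecasts)

    def run(self, refit_each_year: bool = False) -> "EvaluationResults":
        cfg = self.config
        panel, split = self.panel, self.split

        if cfg.subset_size is not None:
            subset_size = cfg.subset_size
        elif cfg.event_fraction is not None:
            subset_size = resolve_subset_size(panel, cfg.event_fraction, split.test_years)
        else:
            subset_size = panel.S
        if not (cfg.k <= subset_size <= panel.S):
            raise ValueError(
                f"need k <= subset_size <= S, got k={cfg.k}, "
                f"subset_size={subset_size}, S={panel.S}"
            )
        subsets = draw_tract_subsets(panel.S, subset_size, cfg.n_subsets, cfg.seed)
        y_true_by_year = {y: panel.counts_for_year(y) for y in split.test_years}

        resolved: dict[str, dict] = {}
        all_forecasts: dict[str, ForecastSet] = {}
        for spec in cfg.models:
            name = spec["name"]
            grid = spec.get("grid", {})
            if grid:
                best = tune_hyperparameters(name, grid, panel, split, cfg.k, seed=cfg.seed)
            else:
                best = dict(spec.get("hyperparams", {}))
            resolved[name] = best
            model = make_model(name, **best)
            fs = forecast_test_years(model, panel, split, refit_each_year=refit_each_year)
            all_forecasts[name] = fs
        for fs in self.external_forecasts:
            all_forecasts[fs.model_name] = fs
            resolved.setdefault(fs.model_name, {"source": "external"})

        summaries: dict[str, dict[str, MetricSummary]] = {}
        true_totals: dict[str, float] = {}
        per_year_totals: dict[str, dict[int, float]] = {}
        for name, fs in all_forecasts.items():
            summaries[name] = resample_metrics(
                y_true_by_year, fs, subsets, cfg.k, metrics=cfg.metrics,
                rng=substream(cfg.seed, "resample", name),
            )
            true_totals[name], per_year_totals[name] = true_total_in_top_k(
                y_true_by_year, fs, cfg.k, rng=substream(cfg.seed, "tally", name),
            )
        table = build_comparison_table(summaries, true_totals)
        return EvaluationResults(
            panel=panel, split=split, config=cfg, subset_size=subset_size,
            forecasts=all_forecasts, summaries=summaries, true_totals=true_totals,
            per_year_totals=per_year_totals, table=table, resolved_hyperparams=resolved,
        )


@dataclass
class EvaluationResults:
    """Everything the evaluation computed, with rendering and save helpers."""

    panel: TractYearPanel
    split: SplitSpec
    config: EvalConfig
    subset_size: int
    forecasts: dict[str, ForecastSet]
    summaries: dict[str, dict[str, MetricSummary]]
    true_totals: dict[str, float]
    per_year_totals: dict[str, dict[int, float]]
    table: ComparisonTable
    resolved_hyperparams: dict[str, dict]

    def summary(self) -> str:
        head = (
            f"Evaluation of {len(self.forecasts)} models on S={self.panel.S} tracts, "
            f"test years {self.split.test_years}; K={self.config.k}, "
            f"{self.config.n_subsets} subsets of {self.subset_size} tracts\n"
        )
        hp = "\n".join(
            f"  {name}: {self.resolved_hyperparams.get(name, {})}"
            for name in self.table.model_names
        )
        return head + "resolved hyperparameters:\n" + hp + "\n\n" + self.table.to_text()

    def samples_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, metrics in self.summaries.items():
            for m, s in metrics.items():
                for year, vals in s.per_year.items():
                    for i, v in enumerate(vals):
                        rows.append({"model": name, "metric": m, "year": year,
                                     "subset_id": i, "value": v})
        return pd.DataFrame(rows)

    def plot_intervals(self, metric: str = "bpr", ax=None):
        """Dot-and-range chart of each model's metric mean and min-max interval."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(self.table.model_names) + 1.5))
        scale = 100.0 if metric == "bpr" else 1.0
        names = self.table.model_names
        for i, name in enumerate(names):
            s = self.summaries[name][metric]
            ax.plot([s.min * scale, s.max * scale], [i, i], color="steelblue", lw=2)
            ax.plot(s.mean * scale, i, "o", color="crimson")
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("%BPR" if metric == "bpr" else metric.upper())
        ax.set_title(f"Resampled {metric} intervals (n={self.config.n_subsets} subsets)")
        ax.figure.tight_layout()
        return ax

    def save(self, out_dir: str | Path) -> None:
        """Write per-sample metrics, predictions, the table and a run log."""
        from .models import write_predictions_csv
        from .panel import write_panel_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples_dataframe().to_csv(out / "metrics_samples.csv", index=False,
                                        float_format="%.10g")
        self.table.to_dataframe().to_csv(out / "comparison_table.csv", index=False)
        (out / "comparison_table.txt").write_text(self.table.to_text() + "\n")
        write_panel_csv(self.panel, out / "panel.csv")
        for name, fs in self.forecasts.items():
            write_predictions_csv(fs, self.panel, out / f"predictions_{name}.csv")
        log = {
            "seed": self.config.seed,
            "k": self.config.k,
            "n_subsets": self.config.n_subsets,
            "subset_size": self.subset_size,
            "split": {"train_years": self.split.train_years,
                      "valid_year": self.split.valid_year,
                      "test_years": self.split.test_years,
                      "lookback_W": self.split.lookback_W},
            "resolved_hyperparams": self.resolved_hyperparams,
            "true_totals": self.true_totals,
            "per_year_totals": {m: {str(y): v for y, v in d.items()}
                                for m, d in self.per_year_totals.items()},
        }
        (out / "run.log").write_text(json.dumps(log, indent=2, default=str) + "\n")


def run_pipeline(
    config: EvalConfig,
    split: SplitSpec,
    panel: TractYearPanel,
    out_dir: str | Path | None = None,
    external_forecasts: Sequence[ForecastSet] = (),
    refit_each_year: bool = False,
) -> EvaluationResults:
    """Convenience wrapper: evaluate, optionally writing all artifacts."""
    results = ReachEvaluation(panel, split, config,
                              external_forecasts=external_forecasts
                              ).run(refit_each_year=refit_each_year)
    if out_dir is not None:
        results.save(out_dir)
    return results
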