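"""Evaluation protocol: tuning, resampling, tables, end-to-end pipeline."""

import numpy as np
import pytest

from reacheval import (
    EvalConfig,
    ForecastSet,
    MetricSummary,
    SplitSpec,
    build_comparison_table,
    draw_tract_subsets,
    forecast_test_years,
    generate_panel,
    make_model,
    make_split,
    preset,
    resample_metrics,
    resolve_subset_size,
    rmse,
    run_pipeline,
    true_total_in_top_k,
    tune_hyperparameters,
)
from reacheval.metrics import bpr, top_k_sum

from conftest import make_panel


def _synth(seed=0, S=100, T=10):
    return generate_panel(preset("persistent-small", seed=seed, S=S, T=T))[0]


def _split(panel, n_train=4, W=3):
    years = panel.years
    return make_split(panel, train_years=years[-(n_train + 3):-3],
                      valid_year=years[-3], test_years=years[-2:], W=W)


class TestMakeSplit:
    def test_state_scale_split_shapes(self):
        panel = make_panel(np.ones((3, 12), dtype=int), first_year=2010)
        s = make_split(panel, train_years=list(range(2011, 2019)), valid_year=2019,
                       test_years=[2020, 2021], W=5)
        assert s.valid_year == 2019 and s.test_years == [2020, 2021]

    def test_test_year_before_validation_rejected(self):
        panel = make_panel(np.ones((3, 12), dtype=int), first_year=2010)
        with pytest.raises(ValueError):
            make_split(panel, train_years=[2011, 2012], valid_year=2013,
                       test_years=[2012], W=1)

    def test_year_missing_from_panel_rejected(self):
        panel = make_panel(np.ones((3, 5), dtype=int), first_year=2010)
        with pytest.raises(ValueError, match="not present"):
            make_split(panel, train_years=[2011, 2012], valid_year=2013,
                       test_years=[2014, 2015], W=1)


class TestTuneHyperparameters:
    def test_single_point_grid_returned_unchanged(self):
        panel = _synth()
        best = tune_hyperparameters("historical_average", {"W": [2]},
                                    panel, _split(panel), k=10, seed=0)
        assert best == {"W": 2}

    def test_tied_scores_prefer_simplest(self):
        # constant panel: every W yields identical validation predictions
        panel = make_panel(np.full((30, 8), 2, dtype=int))
        split = make_split(panel, train_years=[2013, 2014, 2015], valid_year=2016,
                           test_years=[2017], W=3)
        best = tune_hyperparameters("historical_average", {"W": [3, 1, 2]},
                                    panel, split, k=5, seed=0)
        assert best == {"W": 1}

    def test_persistence_favors_recent_windows(self):
        """On AR(1)-persistent panels, validation BPR selects small windows
        more often than the largest one (exhaustive grid evaluation)."""
        small, big = 0, 0
        for seed in range(20):
            panel = _synth(seed=seed, S=80, T=12)
            split = _split(panel, n_train=6, W=6)
            best = tune_hyperparameters("historical_average",
                                        {"W": list(range(1, 7))},
                                        panel, split, k=8, seed=seed)
            if best["W"] <= 3:
                small += 1
            if best["W"] == 6:
                big += 1
        assert small > big

    def test_all_failing_grid_raises(self):
        panel = _synth(S=30, T=6)
        split = make_split(panel, train_years=[2011, 2012], valid_year=2013,
                           test_years=[2014], W=2)
        with pytest.raises(ValueError, match="every grid point failed"):
            tune_hyperparameters("historical_average", {"W": [50, 60]},
                                 panel, split, k=5, seed=0)


class TestSubsets:
    def test_exact_size_distinct_and_reproducible(self):
        a = draw_tract_subsets(100, 80, 50, seed=3)
        b = draw_tract_subsets(100, 80, 50, seed=3)
        for sa, sb in zip(a, b):
            assert len(sa) == 80 and len(np.unique(sa)) == 80
            np.testing.assert_array_equal(sa, sb)

    def test_full_size_subsets_are_the_identity(self):
        for sub in draw_tract_subsets(20, 20, 5, seed=0):
            np.testing.assert_array_equal(sub, np.arange(20))

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            draw_tract_subsets(10, 11, 1, seed=0)

    def test_event_fraction_preserved_in_expectation(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(2.0, size=200).astype(float)
        subsets = draw_tract_subsets(200, 170, 1000, seed=1)
        fracs = np.array([y[s].sum() / y.sum() for s in subsets])
        expect = 170 / 200
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expect) < 3 * se

    def test_resolve_subset_size_rounds_fraction(self):
        panel = make_panel(np.ones((1620, 2), dtype=int),
                           ids=[f"{i:06d}" for i in range(1620)],
                           centroids=np.zeros((1620, 2)))
        assert resolve_subset_size(panel, 0.85) == 1377
        assert resolve_subset_size(panel, 1.0) == 1620


class TestResampleMetrics:
    def _y_by_year(self, panel, years):
        return {y: panel.counts_for_year(y) for y in years}

    def test_full_subset_single_year_collapses_interval(self):
        panel = _synth(S=40, T=8)
        split = make_split(panel, train_years=[2011, 2012, 2013], valid_year=2014,
                           test_years=[2015], W=2)
        fs = forecast_test_years(make_model("historical_average", W=2), panel, split)
        out = resample_metrics(self._y_by_year(panel, [2015]), fs,
                               [np.arange(40)], k=5, rng=np.random.default_rng(0))
        for s in out.values():
            assert s.min == s.mean == s.max

    def test_perfect_foresight_scores_exactly_100(self):
        panel = _synth(S=60, T=8)
        years = panel.years[-2:]
        y_by_year = self._y_by_year(panel, years)
        oracle = ForecastSet(model_name="oracle",
                             predictions={y: y_by_year[y].astype(float)
                                          for y in years})
        subsets = draw_tract_subsets(60, 50, 20, seed=0)
        out = resample_metrics(y_by_year, oracle, subsets, k=8,
                               rng=np.random.default_rng(0))
        assert out["bpr"].min == out["bpr"].max == 1.0
        assert out["rmse"].max == 0.0

    def test_uninformative_model_matches_closed_form_mean(self):
        panel = _synth(S=80, T=8)
        years = panel.years[-2:]
        y_by_year = self._y_by_year(panel, years)
        zeros = ForecastSet(model_name="all_zeros",
                            predictions={y: np.zeros(80) for y in years},
                            uninformative=True)
        subsets = draw_tract_subsets(80, 68, 30, seed=2)
        k = 8
        out = resample_metrics(y_by_year, zeros, subsets, k=k,
                               rng=np.random.default_rng(0))
        expected = np.mean([
            (k / len(sub)) * y_by_year[y][sub].sum() / top_k_sum(y_by_year[y][sub], k)
            for y in years for sub in subsets
        ])
        assert out["bpr"].mean == pytest.approx(expected, abs=1e-12)

    def test_budget_exceeding_subset_rejected(self):
        panel = _synth(S=30, T=8)
        year = panel.years[-1]
        fs = ForecastSet(model_name="m", predictions={year: np.zeros(30)})
        with pytest.raises(ValueError, match="exceeds subset"):
            resample_metrics({year: panel.counts_for_year(year)}, fs,
                             [np.arange(10)], k=15)


class TestTrueTotalInTopK:
    def test_oracle_reaches_hindsight_total(self):
        panel = _synth(S=50, T=8)
        years = panel.years[-2:]
        y_by_year = {y: panel.counts_for_year(y) for y in years}
        oracle = ForecastSet(model_name="oracle",
                             predictions={y: y_by_year[y].astype(float) for y in years})
        mean_total, per_year = true_total_in_top_k(y_by_year, oracle, k=5,
                                                   rng=np.random.default_rng(0))
        expected = np.mean([top_k_sum(y_by_year[y], 5) for y in years])
        assert mean_total == pytest.approx(expected)

    def test_budget_covering_all_tracts_counts_everything(self):
        panel = _synth(S=30, T=8)
        year = panel.years[-1]
        y_by_year = {year: panel.counts_for_year(year)}
        fs = ForecastSet(model_name="m",
                         predictions={year: np.arange(30, dtype=float)})
        mean_total, _ = true_total_in_top_k(y_by_year, fs, k=30)
        assert mean_total == y_by_year[year].sum()

    def test_uninformative_tally_is_inclusion_expectation(self):
        y = np.array([10.0, 0, 0, 0, 0])
        fs = ForecastSet(model_name="z", predictions={2020: np.zeros(5)},
                         uninformative=True)
        mean_total, _ = true_total_in_top_k({2020: y}, fs, k=2)
        assert mean_total == pytest.approx(2 / 5 * 10)


class TestComparisonTable:
    def _summary(self, name, mean, lo, hi):
        return MetricSummary(name=name, values=np.array([lo, mean, hi]))

    def test_single_model_is_best_everywhere(self):
        summaries = {"only": {"bpr": self._summary("bpr", 0.5, 0.4, 0.6),
                              "rmse": self._summary("rmse", 1.0, 0.9, 1.1)}}
        table = build_comparison_table(summaries, {"only": 10.0})
        assert table.best_model == {"bpr": "only", "rmse": "only"}

    def test_overlap_marking_rule_hand_example(self):
        # A mean .60 on [.55,.65]; B mean .62 on [.61,.63]: B best, A marked
        summaries = {
            "A": {"bpr": MetricSummary("bpr", np.array([0.55, 0.60, 0.65]))},
            "B": {"bpr": MetricSummary("bpr", np.array([0.61, 0.62, 0.63]))},
        }
        table = build_comparison_table(summaries, {"A": 1.0, "B": 1.0})
        assert table.best_model["bpr"] == "B"
        assert table.best_marks["bpr"] == {"A", "B"}

    def test_disjoint_interval_below_best_unmarked(self):
        summaries = {
            "low": {"bpr": MetricSummary("bpr", np.array([0.10, 0.15, 0.20]))},
            "high": {"bpr": MetricSummary("bpr", np.array([0.60, 0.62, 0.64]))},
        }
        table = build_comparison_table(summaries, {"low": 0.0, "high": 1.0})
        assert table.best_marks["bpr"] == {"high"}

    def test_text_rendering_precision(self):
        summaries = {
            "m": {"bpr": MetricSummary("bpr", np.array([0.5549, 0.60111, 0.65072])),
                  "rmse": MetricSummary("rmse", np.array([1.234, 1.3, 1.399]))},
        }
        table = build_comparison_table(summaries, {"m": 12.34})
        txt = table.to_text()
        assert "60.2 (55.5-65.1)" in txt  # %BPR to one decimal
        assert "1.31 (1.23-1.40)" in txt  # RMSE to two decimals


class TestRmseBprDivergence:
    def test_rmse_preferred_vector_can_have_lower_bpr(self):
        """Pinned 6-tract instance where the prediction vector preferred by
        RMSE reaches strictly fewer events (lower BPR) than an alternative:
        accurate-but-misranked beats wild-but-well-ranked on error, and
        loses on reach."""
        y_true = np.array([10.0, 9, 0, 0, 0, 0])
        accurate_misranked = np.array([8.0, 8.5, 0, 0, 0, 0])
        wild_wellranked = np.array([30.0, 1, 0, 0, 0, 0])
        k = 1
        rng = np.random.default_rng(0)
        from reacheval import top_k_indices
        bpr_a = bpr(y_true, top_k_indices(accurate_misranked, k, rng=rng))
        bpr_b = bpr(y_true, top_k_indices(wild_wellranked, k, rng=rng))
        assert rmse(y_true, accurate_misranked) < rmse(y_true, wild_wellranked)
        assert bpr_a < bpr_b


class TestRunPipeline:
    def _config(self, seed=0, k=15):
        return EvalConfig(
            k=k, n_subsets=25, subset_size=85, seed=seed,
            models=[
                {"name": "all_zeros"},
                {"name": "historical_average", "grid": {"W": [1, 2, 3]}},
                {"name": "poisson_glm", "hyperparams": {"W": 3}},
            ],
        )

    def test_pipeline_emits_three_row_table_and_artifacts(self, tmp_path):
        panel = _synth(seed=1, S=100, T=10)
        res = run_pipeline(self._config(seed=1), _split(panel), panel,
                           out_dir=tmp_path)
        assert len(res.table.model_names) == 3
        for f in ("metrics_samples.csv", "comparison_table.csv",
                  "comparison_table.txt", "panel.csv", "run.log",
                  "predictions_all_zeros.csv"):
            assert (tmp_path / f).exists()
        assert "%BPR" in res.summary()

    def test_rerun_is_byte_identical(self, tmp_path):
        panel = _synth(seed=2, S=100, T=10)
        a, b = tmp_path / "a", tmp_path / "b"
        run_pipeline(self._config(seed=2, k=10), _split(panel), panel, out_dir=a)
        run_pipeline(self._config(seed=2, k=10), _split(panel), panel, out_dir=b)
        assert (a / "metrics_samples.csv").read_bytes() == \
               (b / "metrics_samples.csv").read_bytes()

    def test_model_bpr_bounded_by_oracle(self):
        panel = _synth(seed=3, S=100, T=10)
        res = run_pipeline(self._config(seed=3, k=10), _split(panel), panel)
        for name in res.table.model_names:
            s = res.summaries[name]["bpr"]
            assert 0.0 <= s.min and s.max <= 1.0

    def test_external_predictions_join_the_table(self, tmp_path):
        panel = _synth(seed=4, S=60, T=10)
        split = _split(panel)
        fs = forecast_test_years(make_model("historical_average", W=2), panel, split)
        fs.model_name = "external_model"
        cfg = EvalConfig(k=10, n_subsets=10, subset_size=50, seed=4,
                         models=[{"name": "all_zeros"}])
        res = run_pipeline(cfg, split, panel, external_forecasts=[fs])
        assert "external_model" in res.table.model_names

    def test_budget_exceeding_tracts_rejected(self):
        panel = _synth(seed=0, S=30, T=10)
        cfg = EvalConfig(k=100, n_subsets=5, subset_size=None, seed=0, models=[])
        with pytest.raises(ValueError, match="exceeds S"):
            run_pipeline(cfg, _split(panel), panel)

    def test_informative_models_beat_all_zeros_under_persistence(self):
        """On the strongly persistent preset the comparison table must rank
        historical average or the GLM above all-zeros on %BPR in at least
        19 of 20 master seeds."""
        wins = 0
        for seed in range(20):
            panel = _synth(seed=seed, S=100, T=10)
            res = run_pipeline(self._config(seed=seed, k=10), _split(panel), panel)
            assert res.table.best_model["bpr"] in ("historical_average", "poisson_glm")
            zeros = res.summaries["all_zeros"]["bpr"].mean
            best = res.summaries[res.table.best_model["bpr"]]["bpr"].mean
            if best > zeros:
                wins += 1
        assert wins >= 19

    def test_plot_intervals_returns_axes(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        panel = _synth(seed=5, S=60, T=10)
        cfg = EvalConfig(k=8, n_subsets=5, subset_size=50, seed=5,
                         models=[{"name": "all_zeros"},
                                 {"name": "historical_average", "hyperparams": {"W": 2}}])
        res = run_pipeline(cfg, _split(panel), panel)
        ax = res.plot_intervals("bpr")
        assert ax.get_xlabel() == "%BPR"
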