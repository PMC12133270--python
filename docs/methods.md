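# Methods

## The evaluation problem

A jurisdiction observes annual counts of fatal opioid-involved overdoses
y[s, t] in each of S census tracts and can afford to intervene in at most
K tracts next year. A forecasting model is useful to the extent that its K
highest-predicted tracts contain the events that actually occur. The
package evaluates model suites for exactly this task: year-based
train/validation/test splits, %BPR-maximising hyperparameter tuning on the
validation year, one-step-ahead rolling forecasts over the test years, and
metric summaries over resampled tract subsets.

## Metrics

For an intervention set I of size K and observed counts y,

- BPR(y, I) = Σ_{i∈I} y_i / Σ_{i∈TopK(y)} y_i, reported as %BPR = 100·BPR
  to one decimal in tables;
- RMSE and MAE are the usual error summaries over all tracts (two
  decimals in tables);
- `reach_fraction_all` divides by the total events over all S tracts
  instead of the top-K sum; it is provided for comparison with the
  alternative used elsewhere in the literature but not used in tables,
  because its maximum depends on the observed data.

Intervention sets take the K highest predictions with uniform random
tie-breaking at the inclusion boundary. The BPR denominator — the sum of
the K largest observed counts — is invariant to which tied tracts
hindsight picks, so ties never make the metric ambiguous.

Degenerate input: a test vector with zero events everywhere makes the
ratio vacuous. It is defined as BPR = 1.0 (any selection reaches all zero
reachable events) and a warning is emitted. This never occurs at realistic
panel scale; the convention only keeps resampled summaries finite on tiny
or degenerate inputs.

Uninformative models (the all-zeros baseline ranks every tract equally)
are scored by the expected reach of uniformly random K-subsets. By
linearity of expectation over uniform inclusion this is exactly
(K/S)·Σy / Σ_TopK y; the pipeline uses this closed form (deterministic and
exact) while `expected_random_bpr` also provides the Monte-Carlo average
over random subsets, cross-checked against the closed form in the test
suite. The true-total-in-top-K tally for uninformative models likewise
uses its expectation (K/S)·Σy.

## The resampling protocol

For each test year, `n_subsets` (default 50) subsets of `subset_size`
tracts are drawn without replacement. Metrics are computed within each
subset — the model's top-K is re-formed inside the subset, so each sample
is a coherent assessment of how the model ranks a distinct set of
locations — and all year × subset values are pooled into one mean and
min–max interval per model and metric (a per-year breakdown is retained in
the samples table). The subset size may be given directly or derived from
a target event fraction; a uniform subset of m tracts preserves m/S of
events in expectation, so the derived size is round(fraction·S) with the
default fraction 0.85.

The comparison table marks the best mean per metric (max for %BPR, min for
RMSE/MAE) and every model whose min–max interval contains that best mean.

## Forecasting models

All families share one contract: `fit(panel, split)` trains on the
training years only; `predict(panel, year)` returns S finite, non-negative
predicted counts, with count-derived features rebuilt from observed data
strictly before the predicted year. Parameters are frozen after training
by default (a `refit_each_year` flag refits with an extended window before
each test year); the second test year always conditions on the first
year's *observed* counts.

- **All-zeros**: predicts 0 everywhere; flagged uninformative.
- **Historical average**: mean of the preceding W years per tract; W is
  the only hyperparameter and is tuned by validation %BPR.
- **Poisson GLM**: log-linear model on lag-1..W counts, centroid lat/lon,
  a time index (years since panel start) and optionally the five SVI
  percentiles. Fitted by Newton/IRLS with step-halving (penalized
  log-likelihood is non-decreasing across iterations), convergence at
  max-gradient < 1e-8 or 100 iterations, and an L2 penalty
  (default ridge = 1e-6, intercept unpenalised) for stability on sparse
  tracts. An all-zero response is rejected outright: the intercept MLE is
  unbounded below and no non-intercept penalty changes that.
- **NBSpLag**: NB2 regression (variance μ + αμ²) adding a spatial-lag
  feature — the mean prior-year count of the tract's n nearest neighbours
  (default n=5) by great-circle centroid distance, with deterministic
  tie-breaking by tract order. Fitted by alternating Fisher-scoring
  updates of the coefficients at fixed α with bounded 1-D profile
  maximisation of α, up to 200 outer iterations, tolerance 1e-7 on the
  log-likelihood, α floored at 1e-8 (the Poisson limit).
- **Gradient-boosted trees**: least-squares boosting on the same design
  (scikit-learn ensemble behind the package's contract); predictions
  clipped at zero, deterministic given seed and hyperparameters.
- **GP / BST / CASTNet**: registry stubs that raise; forecasts from such
  models are scored through the predictions-CSV exchange format
  (tract_id, year, y_pred), so comparison tables can include them.

Continuous non-SVI design columns are standardised with statistics
computed from training rows only and reused verbatim at prediction time.
Count lags enter untransformed; on panels with very heavy-tailed counts a
log-linear model can therefore extrapolate aggressively for extreme
tracts, inflating RMSE while leaving the rank-based %BPR essentially
unaffected — visible for the GLM/NBSpLag rows on the synthetic preset, and
itself an instance of the error-versus-reach divergence the package is
built to expose.

Hyperparameter tuning evaluates each grid point by full-panel %BPR on the
validation year with a fixed tie-break stream; ties prefer the simplest
configuration (smallest W, fewest trees, shallowest depth, then
lexicographic). Grid points that fail to fit are skipped with a warning.

## Synthetic panels

The generator emulates the structure of state-scale overdose-mortality
panels with known ground truth:

    log λ[s, t] = b0 + f(s) + g[s, t] + trend·t + β'·svi[s]

- f is a static Gaussian field with squared-exponential covariance over
  tract centroids (SD `spatial_sd`, length scale `spatial_length_scale`
  in degrees; Euclidean distance in lat/lon is used here since the length
  scale is specified in degrees) — the persistent hotspot surface;
- g[s, ·] is an independent per-tract stationary AR(1) anomaly with
  coefficient `ar_rho` and marginal SD fixed at `spatial_sd`/2 (one fewer
  free scale; at ρ=1 the anomaly freezes and hotspots persist perfectly);
- SVI covariates are exact percentile permutations (rank-transformed
  latent scores with a shared factor and a composite column), constant
  over years, as the published index updates only every five years;
- counts are Poisson(λ), or NB2 with variance λ + `dispersion`·λ² when
  `dispersion` > 0.

Parameter defaults are the "massachusetts-like" preset: S=1000 tracts,
T=21 years, base rate set analytically (lognormal and uniform-covariate
corrections) so the panel-wide mean count is ≈1.2 per tract-year —
emulating the sparsity of roughly two thousand deaths per year over ~1600
tracts — with spatial_sd 0.8, length scale 0.3°, trend +0.05/yr, ar_rho
0.8, svi effects (0.3, 0.1, 0.2, 0.1, 0.3) and dispersion 0.3. These are
an emulation of plausible magnitudes, not a calibration to any restricted
data set. A second preset, "persistent-small" (S=200, T=12, ar_rho=0.95),
is a fast strongly-persistent configuration used for end-to-end checks;
its intervention budget in examples is K=20, preserving the ~10% budget
ratio of K=100 at state scale.

What the generator does *not* emulate: multi-wave supply shifts and other
regime changes, population drift, irregular tract geometries (centroids
only), SVI revisions over time, and reporting artefacts. Tests passing on
synthetic panels therefore demonstrate correctness of the machinery and
qualitative behaviours (persistence rewards informative models; RMSE and
reach can disagree), not performance claims about any real jurisdiction.

## Numerical and design choices

- Panel tract order is sorted tract_id order, fixed at construction; all
  vectors are index-aligned to it. CSV round-trips are exact.
- Tract-years with no events must be explicit zero rows; zero-filling is
  opt-in (`fill_missing_zero`) because silent filling hides data errors.
- Spatial neighbours use k-nearest centroids (great-circle distance)
  rather than polygon contiguity, so adjacency is reproducible from the
  panel alone; the spatial lag uses t−1 counts, the minimal non-leaking
  depth, with n_neighbors and W exposed as hyperparameters.
- SVI values at the target year are treated as exogenous and known ahead
  of time (they are published percentiles, not outcomes); all
  count-derived features use strictly prior years, and a leakage test
  perturbs current/future counts to verify no feature changes.
- Random streams are derived from the single master seed keyed by stage
  and model name, so adding a model never perturbs another model's
  results; pipeline reruns are byte-identical.
- Pooling across test years: per-(year, subset) metric values are pooled
  into one summary, preserving the n-subsets interval semantics while
  covering both years; per-year values are always retained. The
  true-total-in-top-K column is the mean over test years (hence
  non-integer values), with per-year values in the run log.

## Known limitations

- No statistical test beyond interval overlap is attempted for model
  comparison; the min–max interval is a resampling range, not a
  confidence interval.
- The GP, Markov-random-field and neural forecasters are interface stubs;
  their forecasts can be scored but not produced here.
- BPR targets total burden; it does not prioritise rate-of-change or
  equity constraints (an adapted metric could require inclusion of tracts
  with given properties — hook only).
- Log-linear models can over-extrapolate on extreme-count tracts, as noted
  above; users comparing error metrics on heavy-tailed panels should
  inspect per-tract predictions.
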